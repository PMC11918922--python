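"""Reference parsing, anchoring, parsimony merge, lineage nomenclature."""

import pytest

from ylineage import pairtree, refanchor
from ylineage.pairtree import Branch, PhyloTree, build_tree
from ylineage.refanchor import (ReferenceParseError, ReferenceTree,
                                anchor_tree, extend_lineage,
                                load_reference_tree, name_branches,
                                q_backbone_reference)

from conftest import (half_named_reference, match_branches,
                      matrix_from_columns, recovery_config, simulate_matrix,
                      truth_snp_sets)


def make_tree(rows):
    """rows: (id, snps, parent[, carriers])"""
    branches = {}
    for row in rows:
        bid, snps, parent = row[:3]
        carriers = frozenset(row[3]) if len(row) > 3 else frozenset()
        branches[bid] = Branch(id=bid, snps=tuple(snps), parent=parent,
                               carriers=carriers)
    return PhyloTree(branches)


class TestLoadReferenceTree:
    def test_three_row_chain(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("branch\tparent\tsnps\n"
                        "Q1\t\tM242\n"
                        "Q1b\tQ1\tM346\n"
                        "Q1b1\tQ1b\tL53\n")
        ref = load_reference_tree(path)
        assert ref.path("Q1b1") == ["Q1", "Q1b", "Q1b1"]
        assert ref.snp_to_branch() == {"M242": "Q1", "M346": "Q1b", "L53": "Q1b1"}

    def test_undefined_parent_is_error(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("branch\tparent\tsnps\nQ1b\tQ1\tM346\n")
        with pytest.raises(ReferenceParseError, match="Q1"):
            load_reference_tree(path)

    def test_duplicate_snp_name_is_error(self):
        with pytest.raises(ReferenceParseError, match="duplicate SNP"):
            ReferenceTree.from_rows([("Q1", None, ["M242"]),
                                     ("Q1b", "Q1", ["M242"])])

    def test_cycle_is_error(self):
        with pytest.raises(ReferenceParseError):
            ReferenceTree(parents={"A": "B", "B": "A"},
                          snps={"A": frozenset("x"), "B": frozenset("y")})

    def test_q_backbone_nesting(self):
        # the canonical statement: Q1b1-L53 is a sublineage of Q1b-M346
        ref = q_backbone_reference()
        assert ref.is_ancestor("Q1b-M346", "Q1b1-L53")
        assert ref.path("Q1b1a1a1-M848") == [
            "Q-M242", "Q1-L472", "Q1b-M346", "Q1b1-L53",
            "Q1b1a1a-M3", "Q1b1a1a1-M848"]


class TestAnchorTree:
    def test_novel_child_under_named_branch(self):
        inferred = make_tree([("B1", ["M3"], None, ["x", "y"]),
                              ("B2", ["Z9"], "B1", ["x"])])
        ref = ReferenceTree.from_rows([("Q1b1a1a-M3", None, ["M3"])])
        merged = anchor_tree(inferred, ref)
        assert merged.branches["Q1b1a1a-M3"].provenance == "both"
        assert merged.branches["B2"].parent == "Q1b1a1a-M3"
        assert merged.novel_branches == ["B2"]

    def test_empty_reference_returns_inferred_as_novel(self):
        inferred = make_tree([("B1", ["a"], None), ("B2", ["b"], "B1"),
                              ("B3", ["c"], "B1")])
        merged = anchor_tree(inferred, ReferenceTree(parents={}, snps={}))
        assert set(merged.novel_branches) == {"B1", "B2", "B3"}
        for bid in inferred.branches:
            assert merged.branches[bid].parent == inferred.branches[bid].parent

    def test_unobserved_reference_branch_kept_as_passthrough(self):
        inferred = make_tree([("B1", ["M242"], None, ["x"]),
                              ("B2", ["L53"], "B1", ["x"])])
        ref = q_backbone_reference()
        merged = anchor_tree(inferred, ref)
        # unobserved intermediates retained, observed ones promoted
        assert merged.branches["Q1b-M346"].provenance == "database"
        assert merged.branches["Q1b1-L53"].provenance == "both"
        assert merged.path("Q1b1-L53") == [
            "Q-M242", "Q1-L472", "Q1b-M346", "Q1b1-L53"]

    def test_drop_unobserved_prunes_passthrough(self):
        inferred = make_tree([("B1", ["M242"], None, ["x"]),
                              ("B2", ["L53"], "B1", ["x"])])
        merged = anchor_tree(inferred, q_backbone_reference(),
                             keep_unobserved=False)
        assert set(merged.branches) == {"Q-M242", "Q1b1-L53"}
        assert merged.branches["Q1b1-L53"].parent == "Q-M242"

    def test_novel_between_two_anchored_branches(self):
        # data orders M346 > novel > M3; reference knows M346 > M3 only:
        # the novel cluster must be inserted between them
        inferred = make_tree([("B1", ["M346"], None, ["x", "y", "z"]),
                              ("B2", ["n1"], "B1", ["x", "y"]),
                              ("B3", ["M3"], "B2", ["x"])])
        ref = ReferenceTree.from_rows([("Q1b-M346", None, ["M346"]),
                                       ("Q1b1a1a-M3", "Q1b-M346", ["M3"])])
        merged = anchor_tree(inferred, ref)
        assert merged.branches["B2"].parent == "Q1b-M346"
        assert merged.branches["Q1b1a1a-M3"].parent == "B2"

    def test_multi_match_incomparable_reported_unanchored(self):
        inferred = make_tree([("B1", ["M3", "SA1"], None, ["x"])])
        ref = ReferenceTree.from_rows([("Qa", None, ["M3"]),
                                       ("Qb", None, ["SA1"])])
        merged = anchor_tree(inferred, ref)
        assert [c.kind for c in merged.conflicts] == ["multi_match"]
        assert merged.unanchored == [(("M3", "SA1"), "multi_match")]
        assert "B1" not in merged.branches

    def test_nesting_conflict_reference_wins(self):
        # inferred claims M3 above M346; the reference orders them the
        # other way round and must win, with the conflict reported
        inferred = make_tree([("B1", ["M3"], None, ["x", "y"]),
                              ("B2", ["M346"], "B1", ["x"])])
        ref = ReferenceTree.from_rows([("Q1b-M346", None, ["M346"]),
                                       ("Q1b1a1a-M3", "Q1b-M346", ["M3"])])
        merged = anchor_tree(inferred, ref)
        assert merged.branches["Q1b1a1a-M3"].parent == "Q1b-M346"
        assert any(c.kind == "nesting" for c in merged.conflicts)

    def test_anchoring_idempotent(self):
        truth, matrix = simulate_matrix(recovery_config(61))
        result = build_tree(matrix)
        ref, _ = half_named_reference(truth)
        merged = name_branches(anchor_tree(result.tree, ref))
        again = anchor_tree(merged, ref)
        assert set(again.branches) == set(merged.branches)
        for bid in merged.branches:
            a, b = again.branches[bid], merged.branches[bid]
            assert (a.parent, a.provenance, set(a.snps), a.name) == \
                (b.parent, b.provenance, set(b.snps), b.name)

    def test_half_named_simulation_recovers_novel_set(self):
        truth, matrix = simulate_matrix(recovery_config(63))
        result = build_tree(matrix)
        match = match_branches(truth, result.tree)
        ref, named = half_named_reference(truth)
        merged = anchor_tree(result.tree, ref)
        expect_novel = {match[b] for b in range(truth.n_branches)
                        if b not in set(named)}
        assert set(merged.novel_branches) == expect_novel
        assert merged.conflicts == [] and merged.unanchored == []

    def test_variant_conservation_across_pipeline(self):
        # every matrix SNP ends in exactly one of: merged tree, removed
        # report, or the unanchored report
        truth, matrix = simulate_matrix(recovery_config(65, missingness=0.3))
        result = build_tree(matrix)
        ref, _ = half_named_reference(truth)
        merged = anchor_tree(result.tree, ref)
        in_tree = {s for b in merged.branches.values() for s in b.snps}
        removed = {r.label for r in result.removed}
        unanchored = {s for snps, _ in merged.unanchored for s in snps}
        matrix_snps = set(matrix.site_labels)
        assert (in_tree | removed | unanchored) >= matrix_snps
        # a removed matrix SNP may still surface in the merged tree, but
        # only as part of a reference branch's own defining set
        ref_snps = set(ref.snp_to_branch())
        assert (removed & in_tree) <= ref_snps
        assert (unanchored & in_tree) <= ref_snps
        # the inferred tree itself never re-introduces a removed SNP
        inferred_snps = {s for b in result.tree.branches.values() for s in b.snps}
        assert removed.isdisjoint(inferred_snps)


class TestNameBranches:
    def test_alternating_ordinals(self):
        assert extend_lineage("Q1b1a1a", 1) == "Q1b1a1a1"
        assert extend_lineage("Q1b1a1a1", 2) == "Q1b1a1a1b"
        assert extend_lineage("Q", 3) == "Q3"

    def test_first_novel_child_of_m3(self):
        inferred = make_tree([("B1", ["M3"], None, ["x", "y"]),
                              ("B2", ["ZK7"], "B1", ["x"])])
        ref = ReferenceTree.from_rows([("Q1b1a1a-M3", None, ["M3"])])
        merged = name_branches(anchor_tree(inferred, ref))
        assert merged.branches["B2"].name == "Q1b1a1a1-ZK7"

    def test_root_level_novel_uses_configured_prefix(self):
        inferred = make_tree([("B1", ["ZK1"], None, ["x"])])
        merged = name_branches(
            anchor_tree(inferred, ReferenceTree(parents={}, snps={})),
            root_prefix="Q")
        assert merged.branches["B1"].name == "Q1-ZK1"

    def test_sibling_ordinals_distinct_and_deterministic(self):
        inferred = make_tree([
            ("B1", ["M3"], None, ["x", "y", "z"]),
            ("B2", ["ZK2"], "B1", ["x", "y"]),   # more carriers → first
            ("B3", ["ZK1"], "B1", ["z"])])
        ref = ReferenceTree.from_rows([("Q1b1a1a-M3", None, ["M3"])])
        merged = name_branches(anchor_tree(inferred, ref))
        assert merged.branches["B2"].name == "Q1b1a1a1-ZK2"
        assert merged.branches["B3"].name == "Q1b1a1a2-ZK1"

    def test_existing_named_sibling_ordinal_skipped(self):
        inferred = make_tree([("B1", ["M3"], None, ["x", "y"]),
                              ("B2", ["M848"], "B1", ["x"]),
                              ("B3", ["ZK5"], "B1", ["y"])])
        ref = ReferenceTree.from_rows([
            ("Q1b1a1a-M3", None, ["M3"]),
            ("Q1b1a1a1-M848", "Q1b1a1a-M3", ["M848"])])
        merged = name_branches(anchor_tree(inferred, ref))
        # ordinal 1 is taken by the database child Q1b1a1a1-M848
        assert merged.branches["B3"].name == "Q1b1a1a2-ZK5"

    def test_names_unique_across_tree(self):
        truth, matrix = simulate_matrix(recovery_config(67))
        result = build_tree(matrix)
        ref, _ = half_named_reference(truth)
        merged = name_branches(anchor_tree(result.tree, ref))
        names = [b.name for b in merged.branches.values()]
        assert all(names)
        assert len(names) == len(set(names))
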