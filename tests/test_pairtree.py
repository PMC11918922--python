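"""Pairwise classification, filtering, clustering, hierarchy assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ylineage import pairtree, simdata
from ylineage.basecall import CallMatrix, VariantSite
from ylineage.pairtree import (Relation, build_tree, classify_pair,
                               filter_contradictory, group_equivalent,
                               pairwise_relations)

import _oracles
from conftest import (assert_topology_matches, match_branches,
                      matrix_from_columns, recovery_config, simulate_matrix,
                      truth_snp_sets)


class TestClassifyPair:
    @pytest.mark.parametrize("ci,cj,expected", [
        ("DDAA", "DDAA", Relation.EQUIVALENT),
        ("DDAA", "DAAA", Relation.I_ABOVE_J),
        ("DAAA", "DDAA", Relation.J_ABOVE_I),
        ("DDAA", "AADD", Relation.DISJOINT),
        ("DADA", "ADDA", Relation.CONTRADICTORY),
        ("AAAA", "AAAA", Relation.UNINFORMATIVE),
        ("D...", "D...", Relation.UNINFORMATIVE),  # single joint sample
        ("DD..", "..DD", Relation.UNINFORMATIVE),  # no joint samples
    ])
    def test_canonical_patterns(self, ci, cj, expected):
        m = matrix_from_columns([ci, cj])
        assert classify_pair(m, 0, 1).relation == expected

    def test_counts_restricted_to_jointly_called(self):
        m = matrix_from_columns(["DD.A", "DA.D"])
        rel = classify_pair(m, 0, 1)
        assert (rel.n11, rel.n10, rel.n01, rel.n00) == (1, 1, 1, 0)
        assert rel.relation == Relation.CONTRADICTORY

    def test_symmetry_under_swap(self):
        swap = {Relation.I_ABOVE_J: Relation.J_ABOVE_I,
                Relation.J_ABOVE_I: Relation.I_ABOVE_J}
        rng = np.random.default_rng(5)
        for _ in range(200):
            calls = _oracles.random_call_matrix(rng, 8, 2, 0.3)
            m = CallMatrix(
                [f"S{i}" for i in range(8)],
                [VariantSite(position=10 * (j + 1), ref_allele="A",
                             alt_allele="T") for j in range(2)], calls)
            a, b = classify_pair(m, 0, 1), classify_pair(m, 1, 0)
            assert b.relation == swap.get(a.relation, a.relation)
            assert (a.n11, a.n10, a.n01, a.n00) == (b.n11, b.n01, b.n10, b.n00)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_samples = int(rng.integers(4, 11))
            n_sites = int(rng.integers(2, 9))
            p_missing = float(rng.random() * 0.5)
            calls = _oracles.random_call_matrix(rng, n_samples, n_sites, p_missing)
            m = CallMatrix(
                [f"S{i}" for i in range(n_samples)],
                [VariantSite(position=10 * (j + 1), ref_allele="A",
                             alt_allele="T") for j in range(n_sites)], calls)
            codes = pairwise_relations(m)
            for i in range(n_sites):
                for j in range(n_sites):
                    if i == j:
                        continue
                    want = _oracles.brute_classify(calls[:, i], calls[:, j], 2)
                    got = classify_pair(m, i, j).relation.value
                    assert got == want, (calls[:, i], calls[:, j], got, want)
                    assert pairtree._CODE_REL[codes[i, j]].value == want

    def test_identical_sites_rejected(self):
        m = matrix_from_columns(["DDAA", "DDAA"])
        with pytest.raises(ValueError):
            classify_pair(m, 1, 1)

    def test_adding_samples_never_clears_contradiction(self):
        # counts only grow when rows are added
        base = matrix_from_columns(["DADA", "ADDA"])
        assert classify_pair(base, 0, 1).relation == Relation.CONTRADICTORY
        rng = np.random.default_rng(9)
        for _ in range(50):
            extra = _oracles.random_call_matrix(rng, 5, 2, 0.3)
            grown = CallMatrix(
                base.samples + [f"X{i}" for i in range(5)], list(base.sites),
                np.vstack([base.calls, extra]))
            assert classify_pair(grown, 0, 1).relation == Relation.CONTRADICTORY


class TestFilterContradictory:
    def test_clean_input_keeps_everything(self):
        m = matrix_from_columns(["DDDD", "DDAA", "DAAA", "AADD"])
        kept, removed = filter_contradictory(pairwise_relations(m))
        assert kept == [0, 1, 2, 3] and removed == []

    def test_hub_contradictor_removed_first(self):
        # site 0 crosses both others; sites 1 and 2 are cleanly nested
        m = matrix_from_columns(["DADDAA", "DDAAAA", "DDDAAA"])
        codes = pairwise_relations(m)
        assert (codes[0, 1], codes[0, 2]) == (pairtree._CONTRA, pairtree._CONTRA)
        assert codes[1, 2] == pairtree._JAI
        kept, removed = filter_contradictory(codes, m.site_labels)
        assert [r.label for r in removed] == ["s1"]
        assert all(r.reason == "contradictory" for r in removed)
        assert kept == [1, 2]

    def test_mutual_pair_tie_broken_by_site_order(self):
        m = matrix_from_columns(["DADA", "ADDA"])
        kept, removed = filter_contradictory(pairwise_relations(m))
        assert [r.site for r in removed] == [0]
        assert kept == [1]

    def test_recurrent_site_removed_against_truth(self):
        cfg = recovery_config(41)
        truth = simdata.simulate_tree(cfg)
        truth2, pos = simdata.inject_recurrent_site(truth, seed=41)
        _, matrix = simulate_matrix(cfg, truth=truth2)
        kept, removed = filter_contradictory(
            pairwise_relations(matrix), matrix.site_labels)
        assert [r.label for r in removed] == [str(pos)]


class TestGroupEquivalent:
    def test_identical_columns_form_one_cluster(self):
        m = matrix_from_columns(["DDAA", "DDAA", "DDAA", "DAAA"])
        codes = pairwise_relations(m)
        clusters, ambiguous = group_equivalent([0, 1, 2, 3], codes)
        assert sorted(map(tuple, clusters)) == [(0, 1, 2), (3,)]
        assert ambiguous == []

    def test_transitively_glued_inconsistent_cluster_dropped(self):
        # s1 ~ s2 and s2 ~ s3 by pairwise counts, but s1 vs s3 is nested:
        # the closure is internally inconsistent and must be removed
        m = matrix_from_columns(["DAA.A", "D.A.A", "DDA.A"])
        codes = pairwise_relations(m)
        assert codes[0, 1] == codes[1, 2] == pairtree._EQ
        assert codes[0, 2] == pairtree._JAI
        clusters, ambiguous = group_equivalent([0, 1, 2], codes)
        assert clusters == []
        assert {r.site for r in ambiguous} == {0, 1, 2}

    def test_conflicting_external_relations_flag_cluster(self):
        # s1 and s2 look equivalent on joint samples, but s3 is nested
        # inside s1 while disjoint from s2
        m = matrix_from_columns(["DDDAA.", "DD.AAA", "AADAAD"])
        codes = pairwise_relations(m)
        assert codes[0, 1] == pairtree._EQ
        assert codes[0, 2] == pairtree._IAJ
        assert codes[1, 2] == pairtree._DISJ
        clusters, ambiguous = group_equivalent([0, 1, 2], codes)
        assert {r.site for r in ambiguous} >= {0, 1}

    def test_complete_data_cluster_matches_truth_branch(self):
        cfg = recovery_config(43, n_branches=8, per_group=10,
                              mutations_mean=5.0)
        truth, matrix = simulate_matrix(cfg)
        codes = pairwise_relations(matrix)
        clusters, ambiguous = group_equivalent(list(range(matrix.n_sites)), codes)
        assert ambiguous == []
        got = {frozenset(matrix.site_labels[i] for i in c) for c in clusters}
        assert got == set(truth_snp_sets(truth).values())


class TestBuildHierarchy:
    def test_nested_carrier_sets_form_chain(self):
        m = matrix_from_columns(["DDDD", "DDAA", "DAAA"])
        result = build_tree(m)
        tree = result.tree
        assert result.removed == []
        chain = [tree.branches[b] for b in tree.preorder()]
        assert [b.snps for b in chain] == [("s1",), ("s2",), ("s3",)]
        assert [b.parent for b in chain] == [None, "B1", "B2"]

    def test_two_disjoint_children_under_common_ancestor(self):
        m = matrix_from_columns(["DDDD", "DDAA", "AADD"])
        tree = build_tree(m).tree
        kids = tree.children(tree.snp_to_branch()["s1"])
        assert {tree.branches[k].snps for k in kids} == {("s2",), ("s3",)}

    def test_siblings_ordered_by_descending_carrier_count(self):
        m = matrix_from_columns(["DDDDDD", "DAAAAA", "ADDDAA"])
        tree = build_tree(m).tree
        root = tree.snp_to_branch()["s1"]
        kids = tree.children(root)
        assert tree.branches[kids[0]].snps == ("s3",)  # 3 carriers before 1

    def test_exact_recovery_on_complete_noiseless_data(self):
        truth, matrix = simulate_matrix(recovery_config(45))
        result = build_tree(matrix)
        assert result.removed == []
        match = match_branches(truth, result.tree)
        assert_topology_matches(truth, result.tree, match)

    def test_singleton_only_joint_with_carrier_tip_placed(self):
        # s2's carrier is typed nowhere else except its own sample at s1
        m = matrix_from_columns(["DDDAA", "D....", "ADDAA"])
        result = build_tree(m, min_informative=2)
        tree = result.tree
        tip = tree.snp_to_branch().get("s2")
        assert tip is not None
        assert tree.branches[tip].tip_placed
        assert tree.branches[tip].parent == tree.snp_to_branch()["s1"]

    def test_deterministic_given_matrix(self):
        cfg = recovery_config(47, missingness=0.3)
        _, matrix = simulate_matrix(cfg)
        r1, r2 = build_tree(matrix), build_tree(matrix)
        assert r1.tree.to_table().equals(r2.tree.to_table())
        assert [(x.site, x.reason) for x in r1.removed] == \
            [(x.site, x.reason) for x in r2.removed]

    def test_missing_data_output_never_contradicts_counts(self):
        for seed in (51, 52):
            _, matrix = simulate_matrix(recovery_config(seed, n_branches=20,
                                                        per_group=20,
                                                        missingness=0.3))
            result = build_tree(matrix)
            assert pairtree.audit_tree(result.tree, matrix) == []

    def test_snp_conservation_tree_plus_removed(self):
        _, matrix = simulate_matrix(recovery_config(53, missingness=0.3))
        result = build_tree(matrix)
        in_tree = {s for b in result.tree.branches.values() for s in b.snps}
        removed = {r.label for r in result.removed}
        assert in_tree | removed == set(matrix.site_labels)
        assert in_tree & removed == set()


class TestTreeIO:
    def test_tsv_roundtrip(self, tmp_path):
        _, matrix = simulate_matrix(recovery_config(55, n_branches=10,
                                                    per_group=6))
        tree = build_tree(matrix).tree
        path = tmp_path / "tree.tsv"
        tree.to_tsv(path)
        back = pairtree.PhyloTree.from_tsv(path)
        assert set(back.branches) == set(tree.branches)
        for bid in tree.branches:
            assert back.branches[bid].parent == tree.branches[bid].parent
            assert back.branches[bid].snps == tree.branches[bid].snps

    def test_newick_has_all_branches(self, tmp_path):
        import dendropy
        _, matrix = simulate_matrix(recovery_config(57, n_branches=8,
                                                    per_group=5))
        tree = build_tree(matrix).tree
        s = tree.to_newick(tmp_path / "t.nwk", use_names=False)
        dt = dendropy.Tree.get(path=str(tmp_path / "t.nwk"), schema="newick")
        labels = {n.label or (n.taxon.label if n.taxon else None) for n in dt}
        assert labels >= set(tree.branches)
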