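"""Anchor an inferred variant hierarchy to a named reference tree.

Curated Y-haplogroup trees (ISOGG-style tables of branch, parent, and
defining SNP names) supply prior knowledge the pairwise sorting cannot:
lineage names and the established nesting of well-characterised
markers.  Anchoring merges the two sources: inferred clusters that
share a SNP name with a reference branch adopt its name; inferred-only
clusters are inserted below the image of their nearest anchored
ancestor; unobserved reference branches are kept as pass-through nodes
so downstream naming matches database depth.  Where the two sources
disagree on nesting, the reference ordering wins and the conflict is
reported.  "Most parsimonious" is operationalised as inserting the
minimal number of nodes consistent with all non-contradicted pairwise
constraints, with reference precedence on conflict.

Novel branches are then named with the lineage-based (Y Chromosome
Consortium style) nomenclature: the parent's lineage label extended by
an alternating letter/digit child ordinal, hyphenated with the
alphabetically first defining SNP — e.g. the first novel child of
Q1b1a1a-M3 defined by ZK7 becomes Q1b1a1a1-ZK7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .pairtree import Branch, PhyloTree

logger = logging.getLogger(__name__)

_ROOT_MARKERS = {"", "-", "root", "ROOT", "Root", None}


class ReferenceParseError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceTree:
    """A named reference hierarchy: branch → (parent, defining SNP names)."""

    parents: Mapping[str, Optional[str]]
    snps: Mapping[str, FrozenSet[str]]

    def __post_init__(self):
        seen: Set[str] = set()
        for name, parent in self.parents.items():
            if parent is not None and parent not in self.parents:
                raise ReferenceParseError(f"branch {name!r}: undefined parent {parent!r}")
            dup = seen.intersection(self.snps[name])
            if dup:
                raise ReferenceParseError(f"branch {name!r}: duplicate SNP name(s) {sorted(dup)}")
            seen.update(self.snps[name])
        for name in self.parents:  # cycle check
            cur, visited = name, set()
            while cur is not None:
                if cur in visited:
                    raise ReferenceParseError(f"cycle through branch {name!r}")
                visited.add(cur)
                cur = self.parents[cur]

    @property
    def branches(self) -> List[str]:
        return list(self.parents)

    def snp_to_branch(self) -> Dict[str, str]:
        return {s: b for b, ss in self.snps.items() for s in ss}

    def path(self, name: str) -> List[str]:
        out: List[str] = []
        cur: Optional[str] = name
        while cur is not None:
            out.append(cur)
            cur = self.parents[cur]
        return list(reversed(out))

    def depth(self, name: str) -> int:
        return len(self.path(name))

    def is_ancestor(self, anc: str, desc: str) -> bool:
        """True when ``anc`` lies on the root path of ``desc`` (inclusive)."""
        return anc in self.path(desc)

    @classmethod
    def from_rows(cls, rows: Iterable[Tuple[str, Optional[str], Iterable[str]]]
                  ) -> "ReferenceTree":
        parents: Dict[str, Optional[str]] = {}
        snps: Dict[str, FrozenSet[str]] = {}
        for i, (name, parent, snp_names) in enumerate(rows, start=1):
            if name in parents:
                raise ReferenceParseError(f"row {i}: duplicate branch {name!r}")
            snp_set = frozenset(str(s) for s in snp_names if str(s))
            if not snp_set:
                raise ReferenceParseError(f"row {i}: branch {name!r} has no defining SNPs")
            parents[name] = None if parent in _ROOT_MARKERS else parent
            snps[name] = snp_set
        return cls(parents=parents, snps=snps)


def load_reference_tree(path) -> ReferenceTree:
    """Parse a tab-separated reference table with header (branch, parent, snps).

    ``snps`` is a comma-separated list of SNP names; an empty or ``-``
    parent marks a root-level branch.  Validation errors name the
    offending row.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"branch", "parent", "snps"}
    if not required.issubset(df.columns):
        raise ReferenceParseError(f"reference table needs columns {sorted(required)}")
    rows = [(r["branch"], r["parent"], r["snps"].split(","))
            for _, r in df.iterrows()]
    return ReferenceTree.from_rows(rows)


def q_backbone_reference() -> ReferenceTree:
    """The well-established haplogroup-Q backbone used in examples/tests.

    A chain of the canonical markers: Q-M242 > Q1-L472 > Q1b-M346 >
    Q1b1-L53 > Q1b1a1a-M3 > Q1b1a1a1-M848 (Q1b1-L53 is a sublineage of
    Q1b-M346, and M3 defines the major Native American founding
    lineage).
    """
    return ReferenceTree.from_rows([
        ("Q-M242", None, ["M242"]),
        ("Q1-L472", "Q-M242", ["L472"]),
        ("Q1b-M346", "Q1-L472", ["M346"]),
        ("Q1b1-L53", "Q1b-M346", ["L53"]),
        ("Q1b1a1a-M3", "Q1b1-L53", ["M3"]),
        ("Q1b1a1a1-M848", "Q1b1a1a-M3", ["M848"]),
    ])


@dataclass
class AnchorConflict:
    """A nesting disagreement or a multi-match, resolved in the reference's
    favour (or left unanchored) and reported."""

    kind: str                  # 'nesting' or 'multi_match'
    branch: str
    detail: str
    n_carriers: int = 0


@dataclass
class MergedTree(PhyloTree):
    """PhyloTree whose branches carry database/inferred/both provenance."""

    conflicts: List[AnchorConflict] = field(default_factory=list)
    unanchored: List[Tuple[Tuple[str, ...], str]] = field(default_factory=list)

    @property
    def novel_branches(self) -> List[str]:
        return [b.id for b in self.branches.values() if b.provenance == "inferred"]


def anchor_tree(inferred: PhyloTree, ref: ReferenceTree,
                keep_unobserved: bool = True) -> MergedTree:
    """Merge the inferred hierarchy with the reference tree.

    Inferred branches sharing >= 1 SNP name with a reference branch are
    merged into it (provenance ``both``); several matches on one
    ancestor line merge into the deepest; matches to incomparable
    reference branches leave the cluster unanchored and reported.

    The merged topology is the transitive reduction of the combined
    ancestry constraints: the reference's parent links plus the
    inferred tree's parent links mapped through the anchoring.  An
    inferred constraint between two anchored branches that contradicts
    the reference ordering is dropped and reported — the reference
    wins.  Where the combined constraints leave two branches above a
    common descendant unordered (e.g. a pass-through database branch
    and a novel cluster), database branches are placed above novel
    ones, which keeps novel clusters at database depth; any remaining
    ties are ordered deterministically and reported.  With
    ``keep_unobserved=False`` reference branches carrying no observed
    SNP are pruned, children reattaching to the nearest kept ancestor.
    """
    import networkx as nx

    snp_owner = ref.snp_to_branch()
    merged: Dict[str, Branch] = {}
    for name in ref.branches:
        merged[name] = Branch(id=name, snps=tuple(sorted(ref.snps[name])),
                              parent=None, provenance="database", name=name)

    conflicts: List[AnchorConflict] = []
    unanchored: List[Tuple[Tuple[str, ...], str]] = []
    image: Dict[str, str] = {}          # inferred branch id → merged branch id

    for bid in inferred.preorder():
        ib = inferred.branches[bid]
        matches = sorted({snp_owner[s] for s in ib.snps if s in snp_owner},
                         key=ref.depth)
        if not matches:
            continue
        if len(matches) > 1:
            on_line = all(ref.is_ancestor(matches[k], matches[k + 1])
                          for k in range(len(matches) - 1))
            if not on_line:
                conflicts.append(AnchorConflict(
                    kind="multi_match", branch=bid,
                    detail=f"matches incomparable reference branches {matches}",
                    n_carriers=len(ib.carriers)))
                unanchored.append((ib.snps, "multi_match"))
                continue
            logger.info("inferred branch %s matches reference chain %s; merged "
                        "into the deepest", bid, matches)
        target = matches[-1]
        tb = merged[target]
        # a pass-through database branch re-anchored stays 'database';
        # any observed evidence promotes the node to 'both'
        prov = tb.provenance if ib.provenance == "database" else "both"
        # SNPs the reference assigns to a shallower branch of the chain
        # stay there; everything else joins the anchored node
        new_snps = {s for s in ib.snps if snp_owner.get(s, target) == target}
        merged[target] = replace(
            tb, snps=tuple(sorted(set(tb.snps) | new_snps)),
            provenance=prov, carriers=tb.carriers | ib.carriers)
        image[bid] = target

    # novel (inferred-only) branches enter the merged node set as-is
    for bid in inferred.preorder():
        if bid in image:
            continue
        ib = inferred.branches[bid]
        if any(s in snp_owner for s in ib.snps):
            continue  # unanchored multi-match, already reported
        merged[bid] = Branch(id=bid, snps=ib.snps, parent=None,
                             provenance="inferred", name=ib.name,
                             carriers=ib.carriers, tip_placed=ib.tip_placed)
        image[bid] = bid

    def merged_image(bid: Optional[str]) -> Optional[str]:
        while bid is not None:
            if bid in image:
                return image[bid]
            bid = inferred.branches[bid].parent
        return None

    # --- combined ancestry constraint graph (edge u→v: u above v) ----------
    G = nx.DiGraph()
    G.add_nodes_from(merged)
    for name, parent in ref.parents.items():
        if parent is not None:
            G.add_edge(parent, name)
    for bid in inferred.preorder():
        if bid not in image:
            continue
        v = image[bid]
        u = merged_image(inferred.branches[bid].parent)
        if u is None or u == v:
            continue
        both_db = u in ref.parents and v in ref.parents
        if both_db and not ref.is_ancestor(u, v):
            conflicts.append(AnchorConflict(
                kind="nesting", branch=bid,
                detail=(f"inferred nesting places {v} below {u}; "
                        f"reference ordering kept"),
                n_carriers=len(inferred.branches[bid].carriers)))
            continue
        G.add_edge(u, v)

    if not nx.is_directed_acyclic_graph(G):
        # can only arise from degenerate anchorings collapsing one
        # inferred path onto one reference branch; reference edges win
        ref_edges = {(p, n) for n, p in ref.parents.items() if p is not None}
        for scc in nx.strongly_connected_components(G):
            if len(scc) < 2:
                continue
            for u, v in list(G.edges):
                if u in scc and v in scc and (u, v) not in ref_edges:
                    G.remove_edge(u, v)
                    conflicts.append(AnchorConflict(
                        kind="nesting", branch=v,
                        detail=f"cyclic constraint {u}→{v} dropped"))

    # --- reduce to a tree; order residual incomparable ancestors -----------
    def _order_key(node: str) -> Tuple[int, int, str]:
        is_db = 0 if node in ref.parents else 1
        depth = ref.depth(node) if node in ref.parents else 0
        return (is_db, depth, node)

    for _ in range(len(merged) + 1):
        R = nx.transitive_reduction(G)
        multi = sorted(n for n in R.nodes if R.in_degree(n) > 1)
        if not multi:
            break
        for v in multi:
            preds = sorted(R.predecessors(v), key=_order_key)
            added = False
            for a, b in zip(preds, preds[1:]):
                if not G.has_edge(a, b) and not nx.has_path(G, b, a):
                    G.add_edge(a, b)
                    added = True
                    if not (a in ref.parents and b not in ref.parents):
                        conflicts.append(AnchorConflict(
                            kind="ordering", branch=v,
                            detail=f"unordered ancestors {a}, {b}: {a} placed above"))
            if not added:  # defensive; preds were mutually unordered
                G.add_edge(preds[0], preds[1])

    for v in merged:
        preds = list(R.predecessors(v)) if v in R else []
        merged[v].parent = preds[0] if preds else None

    if not keep_unobserved:
        prunable = [b for b in list(merged)
                    if merged[b].provenance == "database"]
        for b in prunable:
            parent = merged[b].parent
            for other in merged.values():
                if other.parent == b:
                    other.parent = parent
            del merged[b]

    return MergedTree(branches=merged, conflicts=conflicts, unanchored=unanchored)


# ---------------------------------------------------------------------------
# lineage-based nomenclature

def _letters(ordinal: int) -> str:
    out = ""
    while ordinal > 0:
        ordinal, rem = divmod(ordinal - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def _letters_to_ordinal(token: str) -> int:
    n = 0
    for ch in token:
        n = n * 26 + (ord(ch) - ord("a") + 1)
    return n


def extend_lineage(parent_label: str, ordinal: int) -> str:
    """Extend a lineage label by one alternating letter/digit level."""
    if not parent_label:
        raise ValueError("parent label must be non-empty")
    if parent_label[-1].isdigit():
        return parent_label + _letters(ordinal)
    return parent_label + str(ordinal)


def _used_ordinals(parent_label: str, sibling_names: Iterable[str]) -> Set[int]:
    used: Set[int] = set()
    expect_digit = not parent_label[-1].isdigit()
    for name in sibling_names:
        if not name or not name.startswith(parent_label):
            continue
        rest = name[len(parent_label):].split("-")[0]
        if not rest:
            continue
        if expect_digit and rest[0].isdigit():
            k = 0
            while k < len(rest) and rest[k].isdigit():
                k += 1
            used.add(int(rest[:k]))
        elif not expect_digit and rest[0].isalpha():
            k = 0
            while k < len(rest) and rest[k].isalpha():
                k += 1
            used.add(_letters_to_ordinal(rest[:k]))
    return used


def name_branches(merged: MergedTree, root_prefix: str = "Q") -> MergedTree:
    """Assign lineage-based names to every novel branch, in place.

    Walks the tree in the deterministic sibling order; each unnamed
    branch gets its parent's lineage label (the part before the SNP
    hyphen; ``root_prefix`` at the top level) extended by the smallest
    alternating-ordinal not used at that lineage level anywhere in the
    tree (database names are historical and keep their ordinals even
    when a novel branch is inserted above them), suffixed with the
    branch's alphabetically first defining SNP.  Names are unique by
    construction.
    """
    for bid in merged.preorder():
        b = merged.branches[bid]
        if b.name is not None:
            continue
        parent = b.parent
        parent_label = root_prefix if parent is None else \
            (merged.branches[parent].name or merged.branches[parent].id).split("-")[0]
        taken = [other.name for other in merged.branches.values() if other.name]
        used = _used_ordinals(parent_label, taken)
        ordinal = 1
        while ordinal in used:
            ordinal += 1
        first_snp = min(b.snps) if b.snps else bid
        b.name = f"{extend_lineage(parent_label, ordinal)}-{first_snp}"
    return merged


def synthetic_reference_rows(parents: Mapping[int, Optional[int]],
                             branch_snps: Mapping[int, Iterable[str]],
                             include: Iterable[int],
                             prefix: str = "Q"
                             ) -> List[Tuple[str, Optional[str], List[str]]]:
    """Build synthetic reference rows naming a subset of known branches.

    Used to stand in for a curated database in simulations: ``include``
    selects the branch ids to name; each named branch's parent is its
    nearest named ancestor, and lineage labels follow the alternating
    letter/digit scheme from ``prefix``.  Returns rows consumable by
    :meth:`ReferenceTree.from_rows`.
    """
    include_set = set(include)
    names: Dict[int, str] = {}
    labels: Dict[Optional[int], str] = {}
    counters: Dict[Optional[int], int] = {}

    def nearest_named(b: Optional[int]) -> Optional[int]:
        while b is not None:
            if b in names:
                return b
            b = parents[b]
        return None

    rows: List[Tuple[str, Optional[str], List[str]]] = []
    order = sorted(include_set, key=lambda b: len(_root_path(parents, b)))
    for b in order:
        anc = nearest_named(parents[b])
        parent_label = prefix if anc is None else names[anc].split("-")[0]
        counters[anc] = counters.get(anc, 0) + 1
        snps = sorted(str(s) for s in branch_snps[b])
        label = f"{extend_lineage(parent_label, counters[anc])}-{snps[0]}"
        names[b] = label
        rows.append((label, names[anc] if anc is not None else None, snps))
    return rows


def _root_path(parents: Mapping[int, Optional[int]], b: int) -> List[int]:
    out = []
    cur: Optional[int] = b
    while cur is not None:
        out.append(cur)
        cur = parents[cur]
    return out
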