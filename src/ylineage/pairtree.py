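"""Pairwise-compatibility tree building for binary variants with missing data.

On a haploid, non-recombining chromosome every variant arises once, so
the derived-carrier sets of any two variants are nested, disjoint, or
identical — never crossing.  With heavy missing data (ancient samples)
the carrier sets are only partially observed, so each pair of sites is
classified from the 2×2 contingency counts over samples called at both:

======================  =======================================
relation                count pattern (n11, n10, n01)
======================  =======================================
equivalent              n11 > 0, n10 = 0, n01 = 0
i_above_j               n11 > 0, n10 > 0, n01 = 0
j_above_i               n11 > 0, n01 > 0, n10 = 0
disjoint                n11 = 0, n10 > 0, n01 > 0
contradictory           n11 > 0, n10 > 0, n01 > 0
uninformative           anything else, or too few joint samples
======================  =======================================

Contradictory patterns (the four-gamete violation, given a known
ancestral state) betray recurrent mutation or calling error; the
offending sites are removed greedily by contradiction count.  Surviving
sites are clustered by transitive equivalence, clusters with ambiguous
relations are dropped, and the remainder are assembled into a rooted
hierarchy via transitive reduction of the above/below DAG.  Everything
is deterministic: ties break by ascending site order, and siblings are
ordered by descending carrier count then site order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .basecall import CallMatrix, ANCESTRAL, DERIVED, MISSING


class Relation(str, Enum):
    UNINFORMATIVE = "uninformative"
    EQUIVALENT = "equivalent"
    I_ABOVE_J = "i_above_j"
    J_ABOVE_I = "j_above_i"
    DISJOINT = "disjoint"
    CONTRADICTORY = "contradictory"


# integer codes for vectorized work
_UNINF, _EQ, _IAJ, _JAI, _DISJ, _CONTRA = 0, 1, 2, 3, 4, 5
_CODE_REL = {_UNINF: Relation.UNINFORMATIVE, _EQ: Relation.EQUIVALENT,
             _IAJ: Relation.I_ABOVE_J, _JAI: Relation.J_ABOVE_I,
             _DISJ: Relation.DISJOINT, _CONTRA: Relation.CONTRADICTORY}

DEFAULT_MIN_INFORMATIVE = 2


@dataclass(frozen=True)
class PairRelation:
    """Classified relationship of one ordered site pair with its counts."""

    site_i: int
    site_j: int
    n11: int
    n10: int
    n01: int
    n00: int
    relation: Relation


def _classify_counts(n11: int, n10: int, n01: int, n00: int,
                     min_informative: int) -> Relation:
    if n11 + n10 + n01 + n00 < min_informative:
        return Relation.UNINFORMATIVE
    if n11 > 0 and n10 == 0 and n01 == 0:
        return Relation.EQUIVALENT
    if n11 > 0 and n10 > 0 and n01 == 0:
        return Relation.I_ABOVE_J
    if n11 > 0 and n01 > 0 and n10 == 0:
        return Relation.J_ABOVE_I
    if n11 == 0 and n10 > 0 and n01 > 0:
        return Relation.DISJOINT
    if n11 > 0 and n10 > 0 and n01 > 0:
        return Relation.CONTRADICTORY
    return Relation.UNINFORMATIVE


def classify_pair(matrix: CallMatrix, i: int, j: int,
                  min_informative: int = DEFAULT_MIN_INFORMATIVE) -> PairRelation:
    """Classify sites ``i`` and ``j`` of the matrix (column indices)."""
    if i == j:
        raise ValueError("classify_pair requires two distinct sites")
    ci, cj = matrix.calls[:, i], matrix.calls[:, j]
    joint = (ci != MISSING) & (cj != MISSING)
    di, dj = ci == DERIVED, cj == DERIVED
    n11 = int((joint & di & dj).sum())
    n10 = int((joint & di & ~dj).sum())
    n01 = int((joint & ~di & dj).sum())
    n00 = int((joint & ~di & ~dj).sum())
    return PairRelation(i, j, n11, n10, n01, n00,
                        _classify_counts(n11, n10, n01, n00, min_informative))


def _pairwise_counts(calls: np.ndarray) -> Tuple[np.ndarray, ...]:
    D = (calls == DERIVED).astype(np.float64)
    A = (calls == ANCESTRAL).astype(np.float64)
    n11 = np.rint(D.T @ D).astype(np.int64)
    n10 = np.rint(D.T @ A).astype(np.int64)  # [i, j]: i derived, j ancestral
    n01 = n10.T
    n00 = np.rint(A.T @ A).astype(np.int64)
    return n11, n10, n01, n00


def pairwise_relations(matrix: CallMatrix,
                       min_informative: int = DEFAULT_MIN_INFORMATIVE) -> np.ndarray:
    """Relation-code matrix over all site pairs (codes as in this module).

    Entry ``[i, j]`` is oriented so that code ``i_above_j`` means site i
    is above site j; the matrix is anti-symmetric under the i↔j swap of
    the two nesting codes.  The diagonal is uninformative.
    """
    n11, n10, n01, n00 = _pairwise_counts(matrix.calls)
    total = n11 + n10 + n01 + n00
    code = np.zeros(n11.shape, dtype=np.int8)
    code[(n11 > 0) & (n10 == 0) & (n01 == 0)] = _EQ
    code[(n11 > 0) & (n10 > 0) & (n01 == 0)] = _IAJ
    code[(n11 > 0) & (n01 > 0) & (n10 == 0)] = _JAI
    code[(n11 == 0) & (n10 > 0) & (n01 > 0)] = _DISJ
    code[(n11 > 0) & (n10 > 0) & (n01 > 0)] = _CONTRA
    code[total < min_informative] = _UNINF
    np.fill_diagonal(code, _UNINF)
    return code


@dataclass(frozen=True)
class RemovedVariant:
    """A site excluded from the hierarchy, with the reason and evidence."""

    site: int          # column index in the matrix
    label: str
    reason: str        # 'contradictory' or 'ambiguous'
    detail: str = ""
    count: int = 0


def filter_contradictory(relations: np.ndarray,
                         labels: Optional[Sequence[str]] = None
                         ) -> Tuple[List[int], List[RemovedVariant]]:
    """Iteratively remove the site with most contradictory partners.

    Ties break by ascending site order (matrix columns are in ascending
    position order).  Returns the kept column indices and the removal
    report with per-site contradiction counts at removal time.
    """
    n = relations.shape[0]
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]
    contra = relations == _CONTRA
    active = np.ones(n, dtype=bool)
    removed: List[RemovedVariant] = []
    while True:
        counts = (contra & active[None, :]).sum(axis=1)
        counts[~active] = 0
        worst = int(counts.max()) if n else 0
        if worst == 0:
            break
        victim = int(np.argmax(counts))  # first max → ascending site order
        active[victim] = False
        removed.append(RemovedVariant(site=victim, label=labels[victim],
                                      reason="contradictory", count=worst))
    return [int(i) for i in np.flatnonzero(active)], removed


def group_equivalent(kept: Sequence[int], relations: np.ndarray
                     ) -> Tuple[List[List[int]], List[RemovedVariant]]:
    """Cluster kept sites by transitive equivalence; drop ambiguous clusters.

    A cluster is ambiguous when (a) two of its members hold conflicting
    definite relations (nested vs disjoint) to the same third site, or
    (b) transitive closure glued together members that are themselves in
    a definite non-equivalent relation.  Ambiguous clusters are removed
    and reported.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    kept = list(kept)
    if not kept:
        return [], []
    sub = relations[np.ix_(kept, kept)]
    eq = sub == _EQ
    n_comp, comp = connected_components(csr_matrix(eq), directed=False)
    clusters: List[List[int]] = [[] for _ in range(n_comp)]
    for local, c in enumerate(comp):
        clusters[c].append(kept[local])
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: c[0])

    ok: List[List[int]] = []
    dropped: List[RemovedVariant] = []
    definite = {_IAJ, _JAI, _DISJ, _CONTRA}
    for cluster in clusters:
        members = np.array(cluster)
        reason = None
        if len(members) > 1:
            internal = relations[np.ix_(members, members)]
            if np.isin(internal, list(definite)).any():
                reason = "internally inconsistent equivalence cluster"
        if reason is None and len(members) >= 1:
            external = np.array([k for k in kept if k not in set(cluster)])
            if external.size:
                rel = relations[np.ix_(members, external)]
                has = np.stack([(rel == c).any(axis=0) for c in (_IAJ, _JAI, _DISJ)])
                if (has.sum(axis=0) > 1).any():
                    reason = "conflicting member relations to a third site"
        if reason is None:
            ok.append(cluster)
        else:
            for s in cluster:
                dropped.append(RemovedVariant(site=int(s), label=str(s),
                                              reason="ambiguous", detail=reason))
    return ok, dropped


@dataclass
class Branch:
    """One branch of the hierarchy, defined by >= 1 equivalent SNPs."""

    id: str
    snps: Tuple[str, ...]
    parent: Optional[str]
    provenance: str = "inferred"       # database | inferred | both
    name: Optional[str] = None
    carriers: FrozenSet[str] = frozenset()
    tip_placed: bool = False

    @property
    def display_name(self) -> str:
        return self.name if self.name else self.id


@dataclass
class PhyloTree:
    """Rooted branch hierarchy; the root is the implicit common ancestor."""

    branches: Dict[str, Branch]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen_snps: Set[str] = set()
        for b in self.branches.values():
            if b.parent is not None and b.parent not in self.branches:
                raise ValueError(f"branch {b.id}: unknown parent {b.parent}")
            dup = seen_snps.intersection(b.snps)
            if dup:
                raise ValueError(f"SNP(s) {sorted(dup)} defined on multiple branches")
            seen_snps.update(b.snps)
        for b in self.branches.values():  # cycle check
            slow = b.id
            seen = set()
            while slow is not None:
                if slow in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(slow)
                slow = self.branches[slow].parent

    def roots(self) -> List[str]:
        return [b.id for b in self.branches.values() if b.parent is None]

    def children(self, branch_id: Optional[str]) -> List[str]:
        kids = [b.id for b in self.branches.values() if b.parent == branch_id]
        kids.sort(key=lambda bid: (-len(self.branches[bid].carriers),
                                   min(self.branches[bid].snps)))
        return kids

    def path(self, branch_id: str) -> List[str]:
        out: List[str] = []
        cur: Optional[str] = branch_id
        while cur is not None:
            out.append(cur)
            cur = self.branches[cur].parent
        return list(reversed(out))

    def depth(self, branch_id: str) -> int:
        """Path length from the (implicit) root; first-level branches are 1."""
        return len(self.path(branch_id))

    def preorder(self) -> List[str]:
        out: List[str] = []
        stack = list(reversed(self.children(None)))
        while stack:
            bid = stack.pop()
            out.append(bid)
            stack.extend(reversed(self.children(bid)))
        return out

    def snp_to_branch(self) -> Dict[str, str]:
        return {s: b.id for b in self.branches.values() for s in b.snps}

    # -- I/O ---------------------------------------------------------------
    def to_table(self):
        import pandas as pd
        rows = []
        for bid in self.preorder():
            b = self.branches[bid]
            rows.append({"branch": bid, "parent": b.parent or "",
                         "name": b.name or "", "snps": ",".join(b.snps),
                         "provenance": b.provenance,
                         "n_carriers": len(b.carriers),
                         "tip_placed": b.tip_placed})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhyloTree":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        branches = {}
        for _, r in df.iterrows():
            branches[r["branch"]] = Branch(
                id=r["branch"], snps=tuple(r["snps"].split(",")) if r["snps"] else (),
                parent=r["parent"] or None, provenance=r.get("provenance", "inferred"),
                name=r["name"] or None,
                tip_placed=str(r.get("tip_placed", "False")) == "True")
        return cls(branches)

    def to_newick(self, path=None, use_names: bool = True) -> str:
        import dendropy
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        nodes = {bid: dendropy.Node(
            label=(self.branches[bid].display_name if use_names else bid))
            for bid in self.branches}
        root = dendropy.Node(label="root")
        tree.seed_node = root
        for bid in self.preorder():
            parent = self.branches[bid].parent
            (nodes[parent] if parent else root).add_child(nodes[bid])
        for leaf in tree.leaf_node_iter():
            leaf.taxon = ns.new_taxon(label=leaf.label)
        tree.is_rooted = True
        s = tree.as_string(schema="newick", suppress_internal_node_labels=False,
                           suppress_rooting=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


@dataclass
class TreeResult:
    """Hierarchy plus the audit trail of everything not placed on it."""

    tree: PhyloTree
    removed: List[RemovedVariant]
    tip_placed: List[str] = field(default_factory=list)


def _merged_columns(calls: np.ndarray, clusters: Sequence[Sequence[int]]) -> np.ndarray:
    merged = np.full((len(clusters), calls.shape[0]), MISSING, dtype=np.int8)
    for c, members in enumerate(clusters):
        sub = calls[:, list(members)]
        any_d = (sub == DERIVED).any(axis=1)
        any_a = (sub == ANCESTRAL).any(axis=1)
        merged[c, any_d] = DERIVED
        merged[c, ~any_d & any_a] = ANCESTRAL
    return merged


def build_hierarchy(matrix: CallMatrix, clusters: Sequence[Sequence[int]],
                    min_informative: int = DEFAULT_MIN_INFORMATIVE
                    ) -> Tuple[PhyloTree, List[RemovedVariant], List[str]]:
    """Assemble ambiguity-filtered clusters into a rooted hierarchy.

    Cluster-level relations are classified on merged cluster columns
    (derived if any member derived, ancestral if any member ancestral
    and none derived).  The above/below DAG is transitively reduced;
    a cluster with more than one immediate dominator admits multiple
    placements and is dropped as ambiguous.  Singleton-carrier clusters
    uninformative against every placed cluster are tip-placed under the
    deepest cluster containing their carrier.  Raises ``RuntimeError``
    if the above/below relation contains a cycle (impossible after
    contradiction filtering).
    """
    import networkx as nx

    labels = matrix.site_labels
    samples = np.array(matrix.samples)
    clusters = [list(c) for c in clusters]
    dropped: List[RemovedVariant] = []
    if not clusters:
        return PhyloTree({}), dropped, []

    merged = _merged_columns(matrix.calls, clusters).T  # samples × clusters
    n11, n10, n01, n00 = _pairwise_counts(merged)
    total = n11 + n10 + n01 + n00
    code = np.zeros(n11.shape, dtype=np.int8)
    code[(n11 > 0) & (n10 == 0) & (n01 == 0)] = _EQ
    code[(n11 > 0) & (n10 > 0) & (n01 == 0)] = _IAJ
    code[(n11 > 0) & (n01 > 0) & (n10 == 0)] = _JAI
    code[(n11 == 0) & (n10 > 0) & (n01 > 0)] = _DISJ
    code[(n11 > 0) & (n10 > 0) & (n01 > 0)] = _CONTRA
    code[total < min_informative] = _UNINF
    np.fill_diagonal(code, _UNINF)

    carriers = [frozenset(samples[matrix.calls[:, list(c)].max(axis=1) == DERIVED])
                for c in clusters]

    active = set(range(len(clusters)))
    # cluster-level contradictions can only appear through missing-data
    # merging; drop the smaller-carrier cluster until clean
    while True:
        pairs = [(a, b) for a in active for b in active
                 if a < b and code[a, b] == _CONTRA]
        if not pairs:
            break
        a, b = pairs[0]
        victim = b if len(carriers[b]) <= len(carriers[a]) else a
        active.discard(victim)
        for s in clusters[victim]:
            dropped.append(RemovedVariant(site=int(s), label=labels[s],
                                          reason="ambiguous",
                                          detail="cluster-level contradiction"))

    # set aside singleton-carrier clusters with no definite relation at all
    tip_candidates = []
    for c in sorted(active):
        others = [o for o in active if o != c]
        if len(carriers[c]) == 1 and all(code[c, o] == _UNINF for o in others):
            tip_candidates.append(c)
    placed = sorted(active.difference(tip_candidates))

    G = nx.DiGraph()
    G.add_nodes_from(placed)
    for a in placed:
        for b in placed:
            if a != b and code[a, b] == _IAJ:
                G.add_edge(a, b)
    if not nx.is_directed_acyclic_graph(G):
        raise RuntimeError("above/below relation contains a cycle")

    while True:
        R = nx.transitive_reduction(G)
        multi = sorted(n for n in R.nodes if R.in_degree(n) > 1)
        if not multi:
            break
        for c in multi:
            G.remove_node(c)
            for s in clusters[c]:
                dropped.append(RemovedVariant(
                    site=int(s), label=labels[s], reason="ambiguous",
                    detail="multiple admissible placements"))
    parent_of: Dict[int, Optional[int]] = {}
    for c in R.nodes:
        preds = list(R.predecessors(c))
        parent_of[c] = preds[0] if preds else None

    # deterministic ids in preorder; siblings by descending carrier count
    kids: Dict[Optional[int], List[int]] = {}
    for c, p in parent_of.items():
        kids.setdefault(p, []).append(c)
    for p in kids:
        kids[p].sort(key=lambda c: (-len(carriers[c]), min(clusters[c])))
    ids: Dict[int, str] = {}
    order: List[int] = []
    stack = list(reversed(kids.get(None, [])))
    while stack:
        c = stack.pop()
        ids[c] = f"B{len(ids) + 1}"
        order.append(c)
        stack.extend(reversed(kids.get(c, [])))

    branches: Dict[str, Branch] = {}
    for c in order:
        p = parent_of[c]
        branches[ids[c]] = Branch(
            id=ids[c], snps=tuple(sorted((labels[s] for s in clusters[c]))),
            parent=ids[p] if p is not None else None,
            carriers=carriers[c])
    tree = PhyloTree(branches)

    # tip placement of orphan singleton clusters
    tip_ids: List[str] = []
    for c in tip_candidates:
        sample = next(iter(carriers[c]))
        hosts = [bid for bid in tree.branches
                 if sample in tree.branches[bid].carriers]
        host = max(hosts, key=lambda bid: (tree.depth(bid), bid)) if hosts else None
        bid = f"B{len(tree.branches) + 1}"
        tree.branches[bid] = Branch(
            id=bid, snps=tuple(sorted(labels[s] for s in clusters[c])),
            parent=host, carriers=carriers[c], tip_placed=True)
        tip_ids.append(bid)
    tree.validate()
    return tree, dropped, tip_ids


def build_tree(matrix: CallMatrix,
               min_informative: int = DEFAULT_MIN_INFORMATIVE,
               snps_only: bool = True) -> TreeResult:
    """Full pipeline: relations → contradiction filter → clustering → hierarchy.

    InDel-class sites are excluded up front by default; they are tallied
    by the QC module but never tree-built.
    """
    work = matrix.snps_only() if snps_only else matrix
    relations = pairwise_relations(work, min_informative)
    kept, removed = filter_contradictory(relations, work.site_labels)
    clusters, ambiguous = group_equivalent(kept, relations)
    removed = removed + [RemovedVariant(site=r.site, label=work.site_labels[r.site],
                                        reason=r.reason, detail=r.detail)
                         for r in ambiguous]
    tree, dropped, tips = build_hierarchy(work, clusters, min_informative)
    return TreeResult(tree=tree, removed=removed + dropped, tip_placed=tips)


def removed_report_tsv(removed: Sequence[RemovedVariant], path) -> None:
    import pandas as pd
    pd.DataFrame([{"site": r.label, "reason": r.reason,
                   "detail": r.detail, "count": r.count}
                  for r in removed]).to_csv(path, sep="\t", index=False)


def audit_tree(tree: PhyloTree, matrix: CallMatrix) -> List[Tuple[str, str, str, str]]:
    """Check every ancestor/descendant branch pair against the raw counts.

    A link is contradicted when some jointly called sample is derived at
    a descendant-defining SNP but ancestral at an ancestor-defining SNP,
    or when the two SNPs' carrier sets are observed disjoint.  Returns
    the list of violations (ancestor branch, descendant branch,
    ancestor SNP, descendant SNP); an empty list is a clean audit.
    """
    col = {lab: j for j, lab in enumerate(matrix.site_labels)}
    calls = matrix.calls
    violations = []
    for bid in tree.branches:
        path = tree.path(bid)[:-1]
        desc_snps = [s for s in tree.branches[bid].snps if s in col]
        for anc_id in path:
            anc_snps = [s for s in tree.branches[anc_id].snps if s in col]
            for sa in anc_snps:
                ca = calls[:, col[sa]]
                for sd in desc_snps:
                    cd = calls[:, col[sd]]
                    joint = (ca != MISSING) & (cd != MISSING)
                    # a descendant carrier observed ancestral at the
                    # ancestor SNP contradicts the nesting claim
                    n01 = int((joint & (ca == ANCESTRAL) & (cd == DERIVED)).sum())
                    if n01 > 0:
                        violations.append((anc_id, bid, sa, sd))
    return violations
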