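"""Haplogroup assignment: place each sample on its deepest supported branch.

A branch is *supported* for a sample when at least one of its defining
SNPs is called derived and the fraction of its typed (non-missing)
defining SNPs called derived reaches ``min_support``.  A branch whose
typed defining SNPs are all ancestral *blocks* descent — missing data
does not (missing is not contradiction), so a supported branch below an
entirely untyped one remains reachable.  The sample is assigned the
deepest supported branch reachable without crossing a blocked branch;
if two supported branches of maximal depth sit on diverging paths
(possible only with conflicting calls), the shallower common ancestor
is reported and the sample flagged.  A sample supporting no branch at
all fails QC.

The default ``min_support`` of 0.95 mirrors the strict base-majority
ethos of the calling thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .basecall import CallMatrix, ANCESTRAL, DERIVED, MISSING
from .pairtree import PhyloTree

_STATE = {"A": ANCESTRAL, "D": DERIVED, ".": MISSING,
          ANCESTRAL: ANCESTRAL, DERIVED: DERIVED, MISSING: MISSING}


@dataclass(frozen=True)
class Assignment:
    """One sample's haplogroup call.

    ``support`` is the derived fraction over the typed defining SNPs of
    the whole root-to-branch path; ``conflicts`` counts typed path SNPs
    called ancestral.  ``status`` is ``assigned`` or ``failed_qc``.
    """

    sample: str
    branch: Optional[str]
    haplogroup: Optional[str]
    depth: int
    support: float
    conflicts: int
    status: str
    flagged: bool = False


def assign_haplogroup(sample: str,
                      calls: Mapping[str, Union[int, str]],
                      tree: PhyloTree,
                      min_support: float = 0.95) -> Assignment:
    """Assign one sample given its SNP-name → call mapping."""
    states = {snp: _STATE[v] for snp, v in calls.items()}

    supported: Dict[str, bool] = {}
    blocked: Dict[str, bool] = {}
    for bid, b in tree.branches.items():
        typed = [states[s] for s in b.snps if states.get(s, MISSING) != MISSING]
        derived = sum(1 for v in typed if v == DERIVED)
        supported[bid] = bool(typed) and derived >= 1 and derived / len(typed) >= min_support
        blocked[bid] = bool(typed) and derived == 0

    reachable_supported: List[str] = []
    stack = [bid for bid in tree.children(None)]
    while stack:
        bid = stack.pop()
        if blocked[bid]:
            continue
        if supported[bid]:
            reachable_supported.append(bid)
        stack.extend(tree.children(bid))

    if not reachable_supported:
        return Assignment(sample=sample, branch=None, haplogroup=None, depth=0,
                          support=0.0, conflicts=0, status="failed_qc")

    max_depth = max(tree.depth(b) for b in reachable_supported)
    deepest = sorted(b for b in reachable_supported if tree.depth(b) == max_depth)
    flagged = False
    if len(deepest) == 1:
        chosen = deepest[0]
    else:
        # conflicting evidence on diverging paths: fall back to the
        # deepest supported branch common to all candidate paths
        paths = [tree.path(b) for b in deepest]
        common = set(paths[0]).intersection(*paths[1:])
        on_path = [b for b in paths[0] if b in common]
        supported_common = [b for b in on_path if supported[b]]
        flagged = True
        if supported_common:
            chosen = supported_common[-1]
        else:
            return Assignment(sample=sample, branch=None, haplogroup=None,
                              depth=0, support=0.0, conflicts=0,
                              status="failed_qc", flagged=True)

    path = tree.path(chosen)
    path_snps = [s for bid in path for s in tree.branches[bid].snps]
    typed = [states[s] for s in path_snps if states.get(s, MISSING) != MISSING]
    derived = sum(1 for v in typed if v == DERIVED)
    conflicts = sum(1 for v in typed if v == ANCESTRAL)
    b = tree.branches[chosen]
    return Assignment(sample=sample, branch=chosen,
                      haplogroup=b.name or chosen, depth=len(path),
                      support=derived / len(typed) if typed else 0.0,
                      conflicts=conflicts, status="assigned", flagged=flagged)


def assign_all(matrix: CallMatrix, tree: PhyloTree,
               min_support: float = 0.95) -> List[Assignment]:
    """Assign every sample of a call matrix."""
    return [assign_haplogroup(s, matrix.sample_calls(s), tree, min_support)
            for s in matrix.samples]


@dataclass(frozen=True)
class ResolutionReport:
    """Comparison of assignment resolution between two marker panels."""

    n_samples: int
    assigned_low: int
    assigned_high: int
    distinct_low: int
    distinct_high: int
    depth_delta: Mapping[str, int]     # per-sample high − low depth

    @property
    def violations(self) -> List[str]:
        return sorted(s for s, d in self.depth_delta.items() if d < 0)


def resolution_report(assignments_low: Sequence[Assignment],
                      assignments_high: Sequence[Assignment],
                      nested_panels: bool = False) -> ResolutionReport:
    """Summarise the resolution gain of a denser marker panel.

    ``assignments_low`` and ``assignments_high`` must cover the same
    samples (otherwise ``ValueError``).  Failed samples contribute depth
    0.  With ``nested_panels=True`` (the high panel's markers contain
    the low panel's) any negative per-sample depth delta raises — the
    gain must be monotone.
    """
    low = {a.sample: a for a in assignments_low}
    high = {a.sample: a for a in assignments_high}
    if set(low) != set(high):
        raise ValueError("assignment sets cover different sample universes")
    delta = {s: high[s].depth - low[s].depth for s in low}
    report = ResolutionReport(
        n_samples=len(low),
        assigned_low=sum(a.status == "assigned" for a in low.values()),
        assigned_high=sum(a.status == "assigned" for a in high.values()),
        distinct_low=len({a.branch for a in low.values() if a.branch is not None}),
        distinct_high=len({a.branch for a in high.values() if a.branch is not None}),
        depth_delta=delta)
    if nested_panels and report.violations:
        raise RuntimeError(
            f"depth decreased for sample(s) {report.violations} although the "
            f"high panel contains the low panel")
    return report


def assignments_tsv(assignments: Sequence[Assignment], path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "sample": a.sample, "haplogroup": a.haplogroup or "",
        "branch": a.branch or "", "depth": a.depth,
        "support": round(a.support, 4), "conflicts": a.conflicts,
        "status": a.status, "flagged": a.flagged,
    } for a in assignments]).to_csv(path, sep="\t", index=False)
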