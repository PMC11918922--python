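"""Capture-enrichment QC and cohort-level variant statistics.

Capture specificity is the ratio of on-target to off-target sequenced
bases per sample.  To find the DNA-input concentration below which
capture becomes unstable, samples are sorted by increasing library
concentration and a stride-1 window of five samples is slid across
them; the mean concentration of the window with the highest spread of
specificities is the stability threshold.  The concentration–
specificity association is summarised by Pearson's r.

Cohort-level statistics operate on the call matrix: the seven-cell
group-sharing partition (which of the three sample groups contain a
derived carrier of each variant), the singleton fraction, SNP/InDel
class tallies, and rounded fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .basecall import CallMatrix, DERIVED
from .simdata import GROUPS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: group label, library DNA concentration
    (ng/µL, optional), on/off-target sequenced base counts, and the
    number of covered bases."""

    sample: str
    group: str
    dna_concentration: Optional[float] = None
    on_target_bases: int = 0
    off_target_bases: int = 0
    covered_bases: int = 0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if min(self.on_target_bases, self.off_target_bases, self.covered_bases) < 0:
            raise ValueError("base counts must be >= 0")


def read_sample_meta(path) -> List[SampleMeta]:
    """Read the sample-metadata TSV (sample, group, dna_concentration,
    on_target_bases, off_target_bases, covered_bases)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        conc = r.get("dna_concentration")
        out.append(SampleMeta(
            sample=str(r["sample"]), group=str(r["group"]),
            dna_concentration=None if pd.isna(conc) else float(conc),
            on_target_bases=int(r.get("on_target_bases", 0)),
            off_target_bases=int(r.get("off_target_bases", 0)),
            covered_bases=int(r.get("covered_bases", 0))))
    return out


def meta_from_frame(df: pd.DataFrame) -> List[SampleMeta]:
    """SampleMeta records from a DataFrame with the standard columns."""
    out = []
    for _, r in df.iterrows():
        conc = r.get("dna_concentration")
        out.append(SampleMeta(
            sample=str(r["sample"]), group=str(r["group"]),
            dna_concentration=None if pd.isna(conc) else float(conc),
            on_target_bases=int(r.get("on_target_bases", 0)),
            off_target_bases=int(r.get("off_target_bases", 0)),
            covered_bases=int(r.get("covered_bases", 0))))
    return out


def capture_specificity(meta: SampleMeta) -> Optional[float]:
    """On-target / off-target sequenced-base ratio; None when undefined
    (zero off-target bases)."""
    if meta.off_target_bases == 0:
        logger.warning("sample %s: zero off-target bases; specificity undefined",
                       meta.sample)
        return None
    return meta.on_target_bases / meta.off_target_bases


@dataclass(frozen=True)
class WindowStat:
    """One five-sample moving window over the concentration-sorted cohort."""

    index: int
    samples: Tuple[str, ...]
    mean_ratio: float
    variation: float
    mean_concentration: float


def window_stats(metas: Sequence[SampleMeta], window: int = 5,
                 variation: str = "sd") -> List[WindowStat]:
    """Stride-1 sliding windows over samples sorted by increasing
    DNA concentration (ties broken by sample id).

    ``variation`` is the per-window spread measure: sample standard
    deviation (``sd``, default), variance (``var``) or coefficient of
    variation (``cv``).  Samples without a concentration or with an
    undefined specificity are excluded; fewer remaining samples than
    the window size is an error.
    """
    if variation not in ("sd", "var", "cv"):
        raise ValueError("variation must be one of 'sd', 'var', 'cv'")
    usable = [(m, capture_specificity(m)) for m in metas
              if m.dna_concentration is not None]
    usable = [(m, r) for m, r in usable if r is not None]
    if len(usable) < window:
        raise ValueError(f"need at least {window} samples with concentration "
                         f"and defined specificity, got {len(usable)}")
    usable.sort(key=lambda mr: (mr[0].dna_concentration, mr[0].sample))

    out: List[WindowStat] = []
    for i in range(len(usable) - window + 1):
        chunk = usable[i:i + window]
        ratios = np.array([r for _, r in chunk], dtype=float)
        concs = np.array([m.dna_concentration for m, _ in chunk], dtype=float)
        sd = float(np.std(ratios, ddof=1))
        if variation == "sd":
            var = sd
        elif variation == "var":
            var = sd ** 2
        else:
            var = sd / float(np.mean(ratios))
        out.append(WindowStat(index=i, samples=tuple(m.sample for m, _ in chunk),
                              mean_ratio=float(np.mean(ratios)), variation=var,
                              mean_concentration=float(np.mean(concs))))
    return out


def concentration_threshold(windows: Sequence[WindowStat]) -> float:
    """Mean concentration of the window with the highest variation
    (ties resolved toward the lowest concentration)."""
    if not windows:
        raise ValueError("need at least one window")
    best = max(windows, key=lambda w: (w.variation, -w.mean_concentration))
    return best.mean_concentration


def concentration_correlation(metas: Sequence[SampleMeta]
                              ) -> Tuple[float, float]:
    """Pearson r (and two-sided p) between DNA concentration and capture
    specificity; ``(nan, nan)`` when either variable is constant."""
    from scipy import stats

    pairs = [(m.dna_concentration, capture_specificity(m)) for m in metas
             if m.dna_concentration is not None]
    pairs = [(c, r) for c, r in pairs if r is not None]
    if len(pairs) < 3:
        raise ValueError("need >= 3 samples with concentration and specificity")
    x = np.array([c for c, _ in pairs])
    y = np.array([r for _, r in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant concentration or specificity; correlation undefined")
        return (math.nan, math.nan)
    res = stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class PartitionResult:
    """Seven-cell group-sharing partition of the cohort's variants."""

    counts: Mapping[str, int]
    total: int

    @property
    def percents(self) -> Dict[str, float]:
        if self.total == 0:
            return {k: math.nan for k in self.counts}
        return {k: 100.0 * v / self.total for k, v in self.counts.items()}


def _cell_label(groups: Iterable[str]) -> str:
    ordered = [g for g in GROUPS if g in set(groups)]
    return "+".join(ordered)


def group_partition(matrix: CallMatrix,
                    metas: Sequence[SampleMeta]) -> PartitionResult:
    """Place each variant into one of the 7 non-empty group subsets
    according to which groups contain >= 1 derived carrier.

    Variants with zero derived carriers violate the matrix invariant;
    they are excluded and logged.
    """
    group_of = {m.sample: m.group for m in metas}
    missing_meta = [s for s in matrix.samples if s not in group_of]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta[:5]}")
    sample_groups = np.array([group_of[s] for s in matrix.samples])

    cells = {}
    for r in range(1, 8):
        subset = [g for k, g in enumerate(GROUPS) if r >> k & 1]
        cells[_cell_label(subset)] = 0
    excluded = 0
    derived = matrix.calls == DERIVED
    for j in range(matrix.n_sites):
        carriers = sample_groups[derived[:, j]]
        if carriers.size == 0:
            excluded += 1
            logger.warning("variant %s has zero derived carriers; excluded",
                           matrix.sites[j].label)
            continue
        cells[_cell_label(set(carriers))] += 1
    return PartitionResult(counts=cells, total=matrix.n_sites - excluded)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_of(count: int, total: int) -> Optional[int]:
    """Integer percentage of ``count`` in ``total`` (half away from zero);
    None when the total is zero."""
    if total == 0:
        return None
    return round_half_away(100.0 * count / total)


def singleton_stats(matrix: CallMatrix) -> Tuple[int, Optional[int]]:
    """Number and integer percentage of variants derived in exactly one
    sample (singletons)."""
    if matrix.n_sites == 0:
        return (0, None)
    counts = (matrix.calls == DERIVED).sum(axis=0)
    n = int((counts == 1).sum())
    return (n, percent_of(n, matrix.n_sites))


def class_tally(sites: Sequence) -> Tuple[int, int, int]:
    """(total, n_SNP, n_InDel) over a collection of variant sites."""
    n_snp = sum(1 for s in sites if s.variant_class == "SNP")
    n_indel = sum(1 for s in sites if s.variant_class == "InDel")
    return (n_snp + n_indel, n_snp, n_indel)


def fold_change(a: float, b: float) -> Optional[int]:
    """``a / b`` rounded to the nearest integer; None when b is zero."""
    if b == 0:
        return None
    return round_half_away(a / b)


def qc_report(metas: Sequence[SampleMeta], window: int = 5,
              variation: str = "sd") -> Dict[str, object]:
    """JSON-ready QC summary: per-sample specificity plus the moving-window
    analysis, stability threshold and Pearson correlation."""
    ratios = {m.sample: capture_specificity(m) for m in metas}
    defined = [r for r in ratios.values() if r is not None]
    windows = window_stats(metas, window=window, variation=variation)
    r, p = concentration_correlation(metas)
    return {
        "n_samples": len(metas),
        "mean_specificity": float(np.mean(defined)) if defined else None,
        "min_specificity": float(np.min(defined)) if defined else None,
        "max_specificity": float(np.max(defined)) if defined else None,
        "concentration_threshold": concentration_threshold(windows),
        "pearson_r": r,
        "pearson_p": p,
        "n_windows": len(windows),
    }
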