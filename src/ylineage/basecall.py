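"""Haploid base-majority variant calling and the ancestral/derived call matrix.

Calling is a deterministic threshold rule, not a likelihood model: reads
below the quality floor are discarded, a site needs a minimum surviving
depth, and the modal base must reach a base-majority fraction of the
surviving reads, otherwise the cell is missing.  Discovery mode (used to
find candidate variant sites) only requires a single quality-passing
non-reference read.  The strict defaults are depth >= 5, quality >= 25,
majority >= 95%; all boundaries are inclusive.

Called bases are polarized against each site's ancestral allele into the
three states ancestral / derived / missing, and sites that are derived
in no sample are dropped, yielding the cohort's polymorphic call matrix
— the central object every downstream module consumes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simdata import PileupColumn, SimulationTruth, ANCESTRAL_BASE

logger = logging.getLogger(__name__)

NAME_TIERS = ("database_tree", "publication", "rs_id", "gnomad", "novel")

#: Call-state codes used in the matrix: ancestral, derived, missing.
ANCESTRAL, DERIVED, MISSING = 0, 1, -1
_STATE_CHAR = {ANCESTRAL: "A", DERIVED: "D", MISSING: "."}
_CHAR_STATE = {v: k for k, v in _STATE_CHAR.items()}


@dataclass(frozen=True)
class CallThresholds:
    """Base-calling thresholds: minimum depth, per-read quality floor,
    and the inclusive base-majority fraction."""

    min_depth: int = 5
    min_quality: int = 25
    base_majority: float = 0.95

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.5 < self.base_majority <= 1.0:
            raise ValueError("base_majority must be in (0.5, 1]")


#: Strict re-calling thresholds: five reads, Q25, 95% majority.
STRICT = CallThresholds(min_depth=5, min_quality=25, base_majority=0.95)
#: Quality floor used when discovering candidate sites (single read suffices).
DISCOVERY_MIN_QUALITY = 25


@dataclass
class VariantSite:
    """A biallelic site with its polarization and annotation.

    ``ancestral_allele`` defaults to the reference allele; it may be
    overridden for known back-mutations and must equal one of the two
    alleles.  ``variant_class`` is SNP iff both alleles are single bases.
    """

    position: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: Optional[str] = None
    name: Optional[str] = None
    name_tier: Optional[str] = None

    def __post_init__(self):
        if self.ancestral_allele is None:
            self.ancestral_allele = self.ref_allele
        if self.ancestral_allele not in (self.ref_allele, self.alt_allele):
            raise ValueError("ancestral_allele must be ref or alt")
        if self.name_tier is not None and self.name_tier not in NAME_TIERS:
            raise ValueError(f"unknown name tier {self.name_tier!r}")

    @property
    def variant_class(self) -> str:
        return "SNP" if len(self.ref_allele) == 1 and len(self.alt_allele) == 1 else "InDel"

    @property
    def derived_allele(self) -> str:
        return self.alt_allele if self.ancestral_allele == self.ref_allele else self.ref_allele

    @property
    def label(self) -> str:
        return self.name if self.name else str(self.position)


def call_base(column: PileupColumn, thresholds: CallThresholds) -> Optional[str]:
    """Call the haploid base for one pileup column, or None (missing).

    Observations below ``min_quality`` are discarded first; the majority
    fraction is computed over the surviving reads.  All thresholds are
    inclusive, so 5 reads at Q25 with 19/20 = 95% agreement pass the
    strict defaults.
    """
    surviving = [a for a, q in column.observations if q >= thresholds.min_quality]
    if len(surviving) < thresholds.min_depth:
        return None
    counts = Counter(surviving)
    # deterministic modal pick; a tie can never reach a majority > 0.5
    base, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    if n / len(surviving) >= thresholds.base_majority:
        return base
    return None


def discover_variants(pileups: Iterable[PileupColumn],
                      ref_alleles: Mapping[int, str],
                      min_quality: int = DISCOVERY_MIN_QUALITY) -> List[VariantSite]:
    """Discover candidate sites: one quality-passing non-reference read suffices.

    The alternate allele at each site is the most frequent non-reference
    allele over all samples (ties broken lexicographically).  Raises
    ``ValueError`` for evidence at a position without a reference allele.
    """
    alt_counts: Dict[int, Counter] = {}
    for col in pileups:
        if col.position not in ref_alleles:
            raise ValueError(f"no reference allele for position {col.position}")
        ref = ref_alleles[col.position]
        for allele, q in col.observations:
            if q >= min_quality and allele != ref:
                alt_counts.setdefault(col.position, Counter())[allele] += 1
    sites = []
    for pos in sorted(alt_counts):
        alt, _ = max(alt_counts[pos].items(), key=lambda kv: (kv[1], kv[0]))
        sites.append(VariantSite(position=pos, ref_allele=ref_alleles[pos], alt_allele=alt))
    return sites


@dataclass(frozen=True)
class AnnotationTable:
    """One annotation source: a tier, a source name, and position → SNP name."""

    tier: str
    source: str
    names: Mapping[int, str]

    def __post_init__(self):
        if self.tier not in NAME_TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


def annotate_variants(sites: Sequence[VariantSite],
                      sources: Sequence[AnnotationTable],
                      novel_prefix: str = "ZK") -> List[VariantSite]:
    """Name sites from the highest-priority tier that covers them.

    Tier priority is database_tree > publication > rs_id > gnomad; sites
    matched by no table get sequential novel identifiers
    (``<prefix>1``, ``<prefix>2``, …) in ascending position order.  Two
    same-tier tables that disagree are logged and the first-listed wins.
    Already-annotated sites keep their name only if a higher- or
    equal-priority source does not rename them identically — re-running
    on the output is a no-op because names are reassigned from the same
    tables deterministically.
    """
    by_tier: Dict[str, List[AnnotationTable]] = {}
    for t in sources:
        by_tier.setdefault(t.tier, []).append(t)

    annotated: List[VariantSite] = []
    unnamed: List[int] = []
    for idx, site in enumerate(sites):
        name = None
        tier_found = None
        for tier in NAME_TIERS[:-1]:
            hits = [(t.source, t.names[site.position])
                    for t in by_tier.get(tier, []) if site.position in t.names]
            if hits:
                names = {n for _, n in hits}
                if len(names) > 1:
                    logger.warning(
                        "conflicting %s names at position %d: %s; keeping %r from %s",
                        tier, site.position,
                        ", ".join(f"{s}:{n}" for s, n in hits), hits[0][1], hits[0][0])
                name, tier_found = hits[0][1], tier
                break
        if name is None:
            annotated.append(replace(site))
            unnamed.append(idx)
        else:
            annotated.append(replace(site, name=name, name_tier=tier_found))

    for k, idx in enumerate(sorted(unnamed, key=lambda i: sites[i].position), start=1):
        annotated[idx] = replace(annotated[idx], name=f"{novel_prefix}{k}",
                                 name_tier="novel")
    return annotated


@dataclass
class CallMatrix:
    """Samples × sites matrix of ancestral/derived/missing calls.

    ``calls`` is int8 with codes 0 (ancestral), 1 (derived), -1
    (missing).  Every retained site is derived in at least one sample.
    """

    samples: List[str]
    sites: List[VariantSite]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape inconsistent with samples/sites")
        if not np.isin(self.calls, (ANCESTRAL, DERIVED, MISSING)).all():
            raise ValueError("calls must be in {0, 1, -1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_labels(self) -> List[str]:
        return [s.label for s in self.sites]

    def sample_calls(self, sample: str) -> Dict[str, int]:
        """Site label → state for one sample."""
        i = self.samples.index(sample)
        return dict(zip(self.site_labels, (int(v) for v in self.calls[i])))

    def subset_sites(self, keep: Sequence[int]) -> "CallMatrix":
        keep = list(keep)
        return CallMatrix(list(self.samples), [self.sites[j] for j in keep],
                          self.calls[:, keep].copy())

    def snps_only(self) -> "CallMatrix":
        """Drop InDel-class sites (they are tallied, never tree-built)."""
        return self.subset_sites([j for j, s in enumerate(self.sites)
                                  if s.variant_class == "SNP"])

    def to_frame(self) -> pd.DataFrame:
        data = np.vectorize(_STATE_CHAR.get)(self.calls) if self.calls.size else \
            np.empty((self.n_samples, 0), dtype=object)
        return pd.DataFrame(data, index=self.samples, columns=self.site_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path, annotation_path=None) -> "CallMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample", dtype=str)
        calls = np.vectorize(_CHAR_STATE.get)(df.to_numpy()) if df.size else \
            np.empty(df.shape, dtype=np.int8)
        if annotation_path is not None:
            ann = read_annotation_tsv(annotation_path)
            by_label = {s.label: s for s in ann}
            sites = [by_label[c] for c in df.columns]
        else:
            sites = []
            for c in df.columns:
                pos = int(c) if str(c).isdigit() else len(sites) + 1
                sites.append(VariantSite(position=pos, ref_allele="A",
                                         alt_allele="T", name=None if str(c).isdigit() else c))
        return cls(list(df.index), sites, calls.astype(np.int8))


def build_call_matrix(pileups: Iterable[PileupColumn],
                      sites: Sequence[VariantSite],
                      thresholds: CallThresholds = STRICT,
                      ancestral: Optional[Mapping[int, str]] = None,
                      samples: Optional[Sequence[str]] = None) -> CallMatrix:
    """Apply the threshold caller per sample × site and polarize the calls.

    A called base that matches neither configured allele is logged and
    treated as missing; sites derived in zero samples (monomorphic after
    filtering) are dropped.  ``ancestral`` optionally overrides the
    per-site ancestral allele (known back-mutations).
    """
    site_map = {s.position: s for s in sites}
    columns: Dict[Tuple[str, int], PileupColumn] = {}
    seen_samples: List[str] = []
    seen = set()
    for col in pileups:
        if col.position not in site_map:
            continue
        columns[(col.sample_id, col.position)] = col
        if col.sample_id not in seen:
            seen.add(col.sample_id)
            seen_samples.append(col.sample_id)
    sample_list = list(samples) if samples is not None else sorted(seen_samples)

    calls = np.full((len(sample_list), len(sites)), MISSING, dtype=np.int8)
    for j, site in enumerate(sites):
        anc = ancestral.get(site.position, site.ancestral_allele) if ancestral else site.ancestral_allele
        der = site.alt_allele if anc == site.ref_allele else site.ref_allele
        for i, sample in enumerate(sample_list):
            col = columns.get((sample, site.position))
            if col is None:
                continue
            base = call_base(col, thresholds)
            if base is None:
                continue
            if base == anc:
                calls[i, j] = ANCESTRAL
            elif base == der:
                calls[i, j] = DERIVED
            else:
                logger.info("sample %s position %d: called base %r matches neither "
                            "allele; treated as missing", sample, site.position, base)
    polymorphic = [j for j in range(len(sites)) if (calls[:, j] == DERIVED).any()]
    return CallMatrix(sample_list, [sites[j] for j in polymorphic],
                      calls[:, polymorphic])


# ---------------------------------------------------------------------------
# readers / writers

def read_pileup_tsv(path) -> Iterator[PileupColumn]:
    """Read the pileup TSV written by the simulator."""
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            sample, pos, bases, quals = line.rstrip("\n").split("\t")
            if bases:
                obs = tuple(zip(bases.split(","), (int(q) for q in quals.split(","))))
            else:
                obs = ()
            yield PileupColumn(sample_id=sample, position=int(pos), observations=obs)


def read_vcf(path, read_quality: int = 60) -> Iterator[PileupColumn]:
    """Expand a minimal haploid VCF (AD/DP annotations) into pileup columns.

    VCF carries no per-read qualities, so every reconstructed read gets
    ``read_quality`` — i.e. AD counts are taken as already
    quality-filtered evidence.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref
            alt = rec.alts[0] if rec.alts else None
            for sample, fmt in rec.samples.items():
                ad = fmt.get("AD")
                if ad is None:
                    continue
                obs = []
                if ad[0]:
                    obs += [(ref, read_quality)] * int(ad[0])
                if alt is not None and len(ad) > 1 and ad[1]:
                    obs += [(alt, read_quality)] * int(ad[1])
                if obs:
                    yield PileupColumn(sample_id=sample, position=rec.pos,
                                       observations=tuple(obs))


def read_position_file(path) -> List[VariantSite]:
    """Read a Yleaf-style position file.

    Tab-separated columns: marker name, chromosome, position, ancestral
    allele, derived allele.  Lines starting with ``#`` are skipped.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("marker", "name"):
                continue
            name, _chrom, pos, anc, der = parts[:5]
            sites.append(VariantSite(position=int(pos), ref_allele=anc,
                                     alt_allele=der, ancestral_allele=anc,
                                     name=name, name_tier="database_tree"))
    return sites


def sites_from_truth(truth: SimulationTruth) -> List[VariantSite]:
    """Variant sites for every mutated position of a simulation truth."""
    return [VariantSite(position=p, ref_allele=ANCESTRAL_BASE,
                        alt_allele=truth.derived_alleles[p])
            for p in truth.positions]


def write_annotation_tsv(sites: Sequence[VariantSite], path) -> None:
    rows = [{"name": s.label, "position": s.position, "ref": s.ref_allele,
             "alt": s.alt_allele, "ancestral": s.ancestral_allele,
             "class": s.variant_class, "tier": s.name_tier or ""}
            for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> List[VariantSite]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "tier": str})
    out = []
    for _, r in df.iterrows():
        tier = r.get("tier")
        tier = None if (pd.isna(tier) or tier == "") else tier
        out.append(VariantSite(position=int(r["position"]), ref_allele=r["ref"],
                               alt_allele=r["alt"], ancestral_allele=r["ancestral"],
                               name=str(r["name"]), name_tier=tier))
    return out
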