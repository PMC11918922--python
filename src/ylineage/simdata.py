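"""Synthetic haploid lineages and capture-sequencing evidence.

This module emulates the data-generating process behind a targeted
Y-chromosome capture study: a rooted paternal-lineage tree on which
binary SNPs arise once (with a small rate of recurrent placements),
three sample groups with very different coverage profiles — modern
admixed (ModAdmix), ancient indigenous (AncNAM, ~90% of sites
uncovered), and modern indigenous (ModNAM) — and noisy per-position
read pileups with a negative-binomial depth model, per-read phred
qualities, and a uniform base-error rate.

Everything is driven by a single master seed; each operation consumes
an independent deterministic substream, so a fixed
:class:`SimulationConfig` reproduces byte-identical output.

The generator also records the full ground truth (tree, branch→mutation
map, sample placements, recurrent sites) so that downstream calling,
tree building and haplogroup assignment can be tested for exact
recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

GROUPS = ("ModAdmix", "AncNAM", "ModNAM")
ANCESTRAL_BASE = "A"
BASES = ("A", "C", "G", "T")

# Study-scale defaults: 277 samples in three groups (130/104/43); a tree of
# 300 branches carrying ~3400 SNPs (≈11.3 per branch); ~1% recurrent sites;
# per-group missingness from the mean covered span of each group relative to
# the best-covered one (ancient samples cover ~1.19 Mb vs ~13.2 Mb).
_DEFAULT_SAMPLES = {"ModAdmix": 130, "AncNAM": 104, "ModNAM": 43}
_DEFAULT_DEPTH = {"ModAdmix": (10.0, 5.0), "AncNAM": (3.0, 2.0), "ModNAM": (15.0, 5.0)}
_DEFAULT_MISSINGNESS = {"ModAdmix": 0.25, "AncNAM": 0.91, "ModNAM": 0.02}


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the lineage-and-sequencing simulator.

    Parameters
    ----------
    n_branches
        Number of branches in the generated tree (>= 2).
    n_samples_per_group
        Samples to attach per group label (ModAdmix / AncNAM / ModNAM).
    mutations_per_branch_mean
        Poisson mean of mutations per branch; every branch carries >= 1.
    recurrence_rate
        Probability that a site is independently placed on a second,
        phylogenetically incomparable branch.
    depth
        Per-group ``(mean, dispersion)`` of a zero-truncated
        negative-binomial read-depth model.
    missingness
        Per-group probability that a sample has no coverage at a site.
    base_error_rate
        Probability a read reports a wrong base.
    quality_mean, quality_sd
        Normal model for per-read phred qualities (rounded, clipped to
        [2, 60]).
    target_span
        Inclusive 1-based interval from which site coordinates are drawn
        without replacement.
    indel_fraction
        Fraction of sites labelled insertion/deletion-class (single-base
        ancestral allele, two-base derived allele); these are counted by
        the QC module but excluded from tree building.
    ensure_branch_coverage
        If true, one sample is pinned to each branch (round-robin over
        the requested samples) before the remainder are attached
        uniformly, guaranteeing every branch has a carrier.
    seed
        Master seed (non-negative integer).
    """

    n_branches: int = 300
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SAMPLES))
    mutations_per_branch_mean: float = 11.3
    recurrence_rate: float = 0.01
    depth: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DEPTH))
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    base_error_rate: float = 0.002
    quality_mean: float = 35.0
    quality_sd: float = 5.0
    target_span: Tuple[int, int] = (1, 7_450_000)
    indel_fraction: float = 0.064
    ensure_branch_coverage: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_branches < 2:
            raise ConfigurationError("n_branches must be >= 2")
        if self.mutations_per_branch_mean <= 0:
            raise ConfigurationError("mutations_per_branch_mean must be > 0")
        for name, p in (("recurrence_rate", self.recurrence_rate),
                        ("base_error_rate", self.base_error_rate),
                        ("indel_fraction", self.indel_fraction)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for g, n in self.n_samples_per_group.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group label {g!r}")
            if n < 0:
                raise ConfigurationError("sample counts must be >= 0")
        for g in self.n_samples_per_group:
            if g not in self.depth or g not in self.missingness:
                raise ConfigurationError(f"no depth/missingness model for group {g!r}")
        for g, (m, k) in self.depth.items():
            if m <= 0 or k <= 0:
                raise ConfigurationError("depth mean and dispersion must be > 0")
        for g, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("missingness must be in [0, 1]")
        lo, hi = self.target_span
        if lo < 1 or hi < lo:
            raise ConfigurationError("target_span must be a 1-based interval")
        if self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated cohort.

    ``parents[b]`` is the parent branch id of branch ``b`` (``None`` for
    the root branch, id 0).  ``branch_mutations[b]`` is the set of site
    coordinates mutated on ``b``; recurrent sites appear on exactly two
    incomparable branches, all other sites on exactly one.
    """

    parents: Tuple[Optional[int], ...]
    branch_mutations: Tuple[FrozenSet[int], ...]
    sample_tip: Mapping[str, int]
    sample_group: Mapping[str, str]
    recurrent_sites: FrozenSet[int]
    derived_alleles: Mapping[int, str]
    indel_sites: FrozenSet[int] = frozenset()

    @property
    def n_branches(self) -> int:
        return len(self.parents)

    @property
    def positions(self) -> Tuple[int, ...]:
        return tuple(sorted(self.derived_alleles))

    @property
    def samples(self) -> Tuple[str, ...]:
        return tuple(sorted(self.sample_tip))

    def root_path(self, branch: int) -> Tuple[int, ...]:
        """Branch ids from the root branch down to ``branch`` inclusive."""
        path = []
        b: Optional[int] = branch
        while b is not None:
            path.append(b)
            b = self.parents[b]
        return tuple(reversed(path))

    def derived_sites(self, sample: str) -> FrozenSet[int]:
        """All sites at which ``sample`` carries the derived allele."""
        out: set = set()
        for b in self.root_path(self.sample_tip[sample]):
            out |= self.branch_mutations[b]
        return frozenset(out)

    def carriers(self, branch: int) -> FrozenSet[int]:
        """Branch ids in the subtree rooted at ``branch`` (inclusive)."""
        children: Dict[int, List[int]] = {}
        for b, p in enumerate(self.parents):
            if p is not None:
                children.setdefault(p, []).append(b)
        stack, sub = [branch], set()
        while stack:
            b = stack.pop()
            sub.add(b)
            stack.extend(children.get(b, ()))
        return frozenset(sub)

    def truth_matrix(self) -> "np.ndarray":
        """Boolean derived-carrier indicator, samples x positions.

        Rows follow :attr:`samples`, columns :attr:`positions`; this is
        the noiseless oracle for the call matrix.
        """
        samples = self.samples
        positions = self.positions
        col = {p: j for j, p in enumerate(positions)}
        out = np.zeros((len(samples), len(positions)), dtype=bool)
        for i, s in enumerate(samples):
            for p in self.derived_sites(s):
                out[i, col[p]] = True
        return out


@dataclass(frozen=True)
class PileupColumn:
    """Per-sample, per-position read evidence.

    ``observations`` is a list of ``(allele, phred_quality)`` pairs and
    may be empty (no coverage).
    """

    sample_id: str
    position: int
    observations: Tuple[Tuple[str, int], ...]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _draw_unique_positions(rng: np.random.Generator, n: int,
                           span: Tuple[int, int]) -> List[int]:
    lo, hi = span
    if hi - lo + 1 < n:
        raise ConfigurationError("target_span too small for requested site count")
    chosen: set = set()
    while len(chosen) < n:
        for p in rng.integers(lo, hi + 1, size=n - len(chosen)):
            chosen.add(int(p))
            if len(chosen) == n:
                break
    return sorted(chosen)


def simulate_tree(config: SimulationConfig) -> SimulationTruth:
    """Grow a random rooted branch hierarchy and place mutations and samples.

    The tree grows by iterative uniform-random attachment: branch ``b``
    (for ``b >= 1``) chooses its parent uniformly among branches
    ``0..b-1``, which yields both chains and polytomies.  Every branch
    carries ``max(1, Poisson(mean))`` mutations at coordinates drawn
    without replacement from the target span.  With probability
    ``recurrence_rate`` a site is additionally placed on a second branch
    that is neither identical to nor on one root-to-tip path with its
    home branch.  Samples are attached to branches uniformly (or pinned
    one-per-branch first when ``ensure_branch_coverage`` is set).
    """
    config.validate()
    rng = _rng(config.seed, 1)
    n = config.n_branches
    parents: List[Optional[int]] = [None]
    for b in range(1, n):
        parents.append(int(rng.integers(0, b)))

    counts = np.maximum(1, rng.poisson(config.mutations_per_branch_mean, size=n))
    positions = _draw_unique_positions(rng, int(counts.sum()), config.target_span)
    muts: List[set] = []
    k = 0
    for b in range(n):
        muts.append(set(positions[k:k + int(counts[b])]))
        k += int(counts[b])

    # ancestor sets for incomparability checks
    truth_paths = []
    for b in range(n):
        path = []
        cur: Optional[int] = b
        while cur is not None:
            path.append(cur)
            cur = parents[cur]
        truth_paths.append(frozenset(path))

    recurrent: set = set()
    if config.recurrence_rate > 0:
        for b in range(n):
            for pos in sorted(muts[b]):
                if pos in recurrent:
                    continue
                if rng.random() >= config.recurrence_rate:
                    continue
                candidates = [c for c in range(n)
                              if c != b and b not in truth_paths[c] and c not in truth_paths[b]]
                if not candidates:
                    continue
                second = candidates[int(rng.integers(len(candidates)))]
                muts[second].add(pos)
                recurrent.add(pos)

    derived: Dict[int, str] = {}
    indel_sites: set = set()
    alts = [b for b in BASES if b != ANCESTRAL_BASE]
    for pos in positions:
        is_indel = rng.random() < config.indel_fraction
        alt = alts[int(rng.integers(3))]
        if is_indel:
            derived[pos] = ANCESTRAL_BASE + alt  # 1 bp insertion
            indel_sites.add(pos)
        else:
            derived[pos] = alt

    sample_tip: Dict[str, int] = {}
    sample_group: Dict[str, str] = {}
    ids: List[Tuple[str, str]] = []
    for g in GROUPS:
        for i in range(config.n_samples_per_group.get(g, 0)):
            ids.append((f"{g}_{i + 1:03d}", g))
    pinned = 0
    if config.ensure_branch_coverage:
        order = rng.permutation(n)
        for (sid, g), b in zip(ids, order):
            sample_tip[sid] = int(b)
            sample_group[sid] = g
            pinned += 1
    for sid, g in ids[pinned:]:
        sample_tip[sid] = int(rng.integers(0, n))
        sample_group[sid] = g

    return SimulationTruth(
        parents=tuple(parents),
        branch_mutations=tuple(frozenset(m) for m in muts),
        sample_tip=sample_tip,
        sample_group=sample_group,
        recurrent_sites=frozenset(recurrent),
        derived_alleles=derived,
        indel_sites=frozenset(indel_sites),
    )


def inject_recurrent_site(truth: SimulationTruth, seed: int = 0
                          ) -> Tuple[SimulationTruth, int]:
    """Place one extra site on two incomparable branches of ``truth``.

    Both branches are chosen (deterministically given ``seed``) among
    branches that have at least one attached sample in their subtree, so
    the new site is guaranteed to surface as a contradictory character
    in the call matrix.  Returns the new truth and the new coordinate.
    """
    rng = _rng(seed, 9)
    occupied = [b for b in range(truth.n_branches)
                if any(truth.sample_tip[s] in truth.carriers(b) for s in truth.samples)]
    pairs = []
    paths = [frozenset(truth.root_path(b)) for b in range(truth.n_branches)]
    for i, b1 in enumerate(occupied):
        for b2 in occupied[i + 1:]:
            if b1 not in paths[b2] and b2 not in paths[b1]:
                pairs.append((b1, b2))
    if not pairs:
        raise ValueError("tree has no incomparable occupied branch pair")
    b1, b2 = pairs[int(rng.integers(len(pairs)))]
    pos = max(truth.positions) + 1
    muts = [set(m) for m in truth.branch_mutations]
    muts[b1].add(pos)
    muts[b2].add(pos)
    derived = dict(truth.derived_alleles)
    derived[pos] = "T"
    return dataclasses.replace(
        truth,
        branch_mutations=tuple(frozenset(m) for m in muts),
        recurrent_sites=truth.recurrent_sites | {pos},
        derived_alleles=derived,
    ), pos


class MetadataError(KeyError):
    """Raised for samples whose group has no configured model."""


def _zero_truncated_nb(rng: np.random.Generator, mean: float, dispersion: float,
                       size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    d = rng.negative_binomial(dispersion, p, size=size)
    for _ in range(1000):
        zeros = d == 0
        if not zeros.any():
            break
        d[zeros] = rng.negative_binomial(dispersion, p, size=int(zeros.sum()))
    d[d == 0] = 1
    return d


def simulate_pileups(truth: SimulationTruth,
                     config: SimulationConfig) -> Iterator[PileupColumn]:
    """Emit noisy pileup columns for every sample x covered site.

    For each sample and site, the site is covered with probability
    ``1 - missingness[group]``; covered sites get a zero-truncated
    negative-binomial read depth, reads report the sample's true allele
    flipped with ``base_error_rate``, and qualities are drawn from the
    normal quality model.  Uncovered sites emit no column — for the
    AncNAM group this is the dominant outcome.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    positions = truth.positions
    nsites = len(positions)
    for sample in truth.samples:
        group = truth.sample_group[sample]
        if group not in config.missingness or group not in config.depth:
            raise MetadataError(f"no model configured for group {group!r}")
        miss = config.missingness[group]
        mean, disp = config.depth[group]
        covered = rng.random(nsites) >= miss
        depths = _zero_truncated_nb(rng, mean, disp, nsites)
        derived = truth.derived_sites(sample)
        for j in np.flatnonzero(covered):
            pos = positions[j]
            depth = int(depths[j])
            true_allele = truth.derived_alleles[pos] if pos in derived else ANCESTRAL_BASE
            quals = np.clip(np.rint(rng.normal(config.quality_mean,
                                               config.quality_sd, depth)), 2, 60)
            alleles = [true_allele] * depth
            if config.base_error_rate > 0:
                err = rng.random(depth) < config.base_error_rate
                wrong = [b for b in BASES if b != true_allele]
                for k in np.flatnonzero(err):
                    alleles[k] = wrong[int(rng.integers(len(wrong)))]
            obs = tuple(zip(alleles, (int(q) for q in quals)))
            yield PileupColumn(sample_id=sample, position=int(pos), observations=obs)


def simulate_capture_meta(n_samples: int = 59, seed: int = 0,
                          concentration_range: Tuple[float, float] = (0.2, 9.2),
                          base_ratio: float = 0.93, slope: float = 0.03,
                          noisy_sd: float = 0.45, stable_sd: float = 0.12,
                          noise_threshold: float = 0.6,
                          low_input_factor: float = 0.8,
                          group: str = "ModAdmix") -> "pd.DataFrame":
    """Synthetic capture-enrichment metadata for the QC module.

    Emulates a capture cohort in which the on/off-target base ratio
    averages ~1.0 and rises mildly with library-input DNA
    concentration; concentrations are log-uniform over the configured
    range (library inputs skew low), and below ``noise_threshold`` the
    ratio is both depressed (``low_input_factor``) and far more
    variable — the unstable low-input regime the QC window statistics
    are designed to detect.  Returns a DataFrame with the columns the
    qcstats readers expect.
    """
    import pandas as pd

    rng = _rng(seed, 3)
    lo, hi = concentration_range
    conc = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples)))
    noisy = conc < noise_threshold
    mu = np.where(noisy, base_ratio * low_input_factor,
                  base_ratio + slope * conc)
    sd = np.where(noisy, noisy_sd, stable_sd)
    ratio = np.clip(rng.normal(mu, sd), 0.05, 1.5)
    total = rng.uniform(2e7, 2e8, n_samples)
    on = total * ratio / (1.0 + ratio)
    off = total - on
    covered = np.clip(rng.normal(9.9e6, 2.5e6, n_samples), 2.5e6, 1.77e7)
    return pd.DataFrame({
        "sample": [f"{group}_{i + 1:03d}" for i in range(n_samples)],
        "group": group,
        "dna_concentration": np.round(conc, 3),
        "on_target_bases": on.astype(np.int64),
        "off_target_bases": off.astype(np.int64),
        "covered_bases": covered.astype(np.int64),
    })


# ---------------------------------------------------------------------------
# writers

def write_pileup_tsv(columns: Iterable[PileupColumn], path) -> None:
    """Write pileup columns as TSV: sample, position, bases, qualities."""
    with open(path, "w") as fh:
        fh.write("sample\tposition\tbases\tqualities\n")
        for col in columns:
            bases = ",".join(b for b, _ in col.observations)
            quals = ",".join(str(q) for _, q in col.observations)
            fh.write(f"{col.sample_id}\t{col.position}\t{bases}\t{quals}\n")


def write_vcf(columns: Iterable[PileupColumn], truth: SimulationTruth, path) -> None:
    """Write the evidence as a minimal haploid VCF on pseudo-contig chrY.

    Each record carries per-sample DP and AD (ref, alt read counts after
    no filtering) plus a haploid GT set to the raw modal allele; per-read
    qualities are not representable in VCF, so consumers of this file
    treat the AD counts as already quality-filtered.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=chrY,length=59373566>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    samples = truth.samples
    for s in samples:
        header.add_sample(s)

    by_pos: Dict[int, Dict[str, Tuple[Tuple[str, int], ...]]] = {}
    for col in columns:
        by_pos.setdefault(col.position, {})[col.sample_id] = col.observations

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for pos in sorted(by_pos):
            ref = ANCESTRAL_BASE
            alt = truth.derived_alleles.get(pos)
            if alt is None or alt == ref:
                continue
            rec = vf.new_record(contig="chrY", start=pos - 1,
                                stop=pos - 1 + len(ref), alleles=(ref, alt))
            for s in samples:
                obs = by_pos[pos].get(s, ())
                n_ref = sum(1 for a, _ in obs if a == ref)
                n_alt = sum(1 for a, _ in obs if a == alt)
                fmt = rec.samples[s]
                fmt["DP"] = len(obs)
                fmt["AD"] = (n_ref, n_alt)
                if n_alt > 0 and n_alt >= n_ref:
                    fmt["GT"] = (1,)
                elif n_ref > 0:
                    fmt["GT"] = (0,)
                else:
                    fmt["GT"] = (None,)
            vf.write(rec)


def write_truth_newick(truth: SimulationTruth, path) -> None:
    """Write the generating branch hierarchy as newick (labels ``B<i>``)."""
    import dendropy

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = {b: dendropy.Node(label=f"B{b}") for b in range(truth.n_branches)}
    for b, p in enumerate(truth.parents):
        if p is None:
            tree.seed_node = nodes[b]
        else:
            nodes[p].add_child(nodes[b])
    for leaf in tree.leaf_node_iter():
        leaf.taxon = ns.new_taxon(label=leaf.label)
    tree.is_rooted = True
    tree.write(path=str(path), schema="newick",
               suppress_internal_node_labels=False, suppress_rooting=True)


def write_branch_mutations_tsv(truth: SimulationTruth, path) -> None:
    """Write the branch → mutation map as TSV."""
    with open(path, "w") as fh:
        fh.write("branch\tparent\tpositions\trecurrent\n")
        for b in range(truth.n_branches):
            parent = "" if truth.parents[b] is None else f"B{truth.parents[b]}"
            pos = ",".join(str(p) for p in sorted(truth.branch_mutations[b]))
            rec = ",".join(str(p) for p in sorted(truth.branch_mutations[b] & truth.recurrent_sites))
            fh.write(f"B{b}\t{parent}\t{pos}\t{rec}\n")
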