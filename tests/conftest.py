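"""Shared fixtures and helpers for the ylineage test suite."""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from ylineage import basecall, pairtree, refanchor, simdata
from ylineage.basecall import CallMatrix, VariantSite
from ylineage.simdata import GROUPS, PileupColumn, SimulationConfig, SimulationTruth

# Depth model used for "complete data" runs: effectively Poisson(30), so
# the probability of dipping below the strict minimum depth of five is
# negligible (< 1e-8 per column) and coverage is controlled by the
# missingness parameter alone.
DEEP = {g: (30.0, 1000.0) for g in GROUPS}
NO_MISS = {g: 0.0 for g in GROUPS}


def matrix_from_columns(columns: Sequence[str],
                        samples: Optional[Sequence[str]] = None) -> CallMatrix:
    """Build a CallMatrix from per-site strings of 'D'/'A'/'.'.

    ``columns[j][i]`` is sample i's state at site j; sites are named
    "s1", "s2", ... and given synthetic ascending positions.
    """
    n_samples = len(columns[0])
    assert all(len(c) == n_samples for c in columns)
    samples = list(samples) if samples else [f"S{i + 1}" for i in range(n_samples)]
    code = {"D": 1, "A": 0, ".": -1}
    calls = np.array([[code[c[i]] for c in columns] for i in range(n_samples)],
                     dtype=np.int8)
    sites = [VariantSite(position=10 * (j + 1), ref_allele="A", alt_allele="T",
                         name=f"s{j + 1}") for j in range(len(columns))]
    return CallMatrix(samples, sites, calls)


def recovery_config(seed: int, *, n_branches: int = 30, per_group: int = 40,
                    mutations_mean: float = 3.0, missingness: float = 0.0,
                    error_rate: float = 0.0, recurrence: float = 0.0
                    ) -> SimulationConfig:
    """Study-shaped config scaled for recovery testing: full branch
    coverage, deep (effectively Poisson-30) depth, SNPs only."""
    return SimulationConfig(
        n_branches=n_branches,
        n_samples_per_group={g: per_group for g in GROUPS},
        mutations_per_branch_mean=mutations_mean,
        recurrence_rate=recurrence,
        depth=DEEP,
        missingness={g: missingness for g in GROUPS},
        base_error_rate=error_rate,
        indel_fraction=0.0,
        ensure_branch_coverage=True,
        seed=seed)


def simulate_matrix(config: SimulationConfig,
                    truth: Optional[SimulationTruth] = None
                    ) -> Tuple[SimulationTruth, CallMatrix]:
    """simulate → pileups → strict call matrix (all samples retained)."""
    if truth is None:
        truth = simdata.simulate_tree(config)
    columns = simdata.simulate_pileups(truth, config)
    matrix = basecall.build_call_matrix(
        columns, basecall.sites_from_truth(truth), basecall.STRICT,
        samples=list(truth.samples))
    return truth, matrix


def truth_snp_sets(truth: SimulationTruth) -> Dict[int, FrozenSet[str]]:
    """Branch id → set of site labels (labels are string positions)."""
    return {b: frozenset(str(p) for p in truth.branch_mutations[b])
            for b in range(truth.n_branches)}


def match_branches(truth: SimulationTruth,
                   tree: pairtree.PhyloTree) -> Dict[int, str]:
    """Map each truth branch to the recovered branch with the same SNP set.

    Raises ``KeyError`` if any truth branch has no exact counterpart.
    """
    by_snps = {frozenset(b.snps): b.id for b in tree.branches.values()}
    out = {}
    for b, snps in truth_snp_sets(truth).items():
        if snps not in by_snps:
            raise KeyError(f"truth branch {b} (SNPs {sorted(snps)}) not recovered")
        out[b] = by_snps[snps]
    return out


def assert_topology_matches(truth: SimulationTruth,
                            tree: pairtree.PhyloTree,
                            match: Dict[int, str]) -> None:
    """Parent structure of the recovered tree equals the truth's."""
    for b, parent in enumerate(truth.parents):
        want = None if parent is None else match[parent]
        got = tree.branches[match[b]].parent
        assert got == want, f"branch {b}: parent {got!r}, expected {want!r}"


def half_named_reference(truth: SimulationTruth,
                         named: Optional[Sequence[int]] = None
                         ) -> Tuple[refanchor.ReferenceTree, List[int]]:
    """A synthetic reference naming every other truth branch."""
    if named is None:
        named = list(range(0, truth.n_branches, 2))
    rows = refanchor.synthetic_reference_rows(
        dict(enumerate(truth.parents)),
        {b: s for b, s in truth_snp_sets(truth).items()}, named)
    return refanchor.ReferenceTree.from_rows(rows), list(named)


@pytest.fixture(scope="session")
def q_backbone() -> refanchor.ReferenceTree:
    return refanchor.q_backbone_reference()


@pytest.fixture(scope="session")
def small_cohort() -> Tuple[SimulationTruth, CallMatrix]:
    """One deep, complete, noiseless cohort reused by read-only tests."""
    return simulate_matrix(recovery_config(101))
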