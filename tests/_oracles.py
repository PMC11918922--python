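"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a statistic or classification by the most direct
means available (explicit set comparison, two-pass formulas, exhaustive
tallies) so the production code paths are checked against logic that
shares nothing with them.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np


def brute_classify(col_i: Sequence[int], col_j: Sequence[int],
                   min_informative: int) -> str:
    """Classify a site pair by explicit carrier-set comparison.

    Columns use codes 1 (derived), 0 (ancestral), -1 (missing).  The
    relation is read off the derived-carrier sets restricted to samples
    called at both sites.
    """
    joint = [k for k in range(len(col_i)) if col_i[k] != -1 and col_j[k] != -1]
    if len(joint) < min_informative:
        return "uninformative"
    di = {k for k in joint if col_i[k] == 1}
    dj = {k for k in joint if col_j[k] == 1}
    if not di and not dj:
        return "uninformative"
    if di and di == dj:
        return "equivalent"
    if di and dj and not di & dj:
        return "disjoint"
    if di & dj:
        if dj < di:
            return "i_above_j"
        if di < dj:
            return "j_above_i"
        return "contradictory"
    # one carrier set empty, the other not: no pattern applies
    return "uninformative"


def brute_sd(values: Sequence[float]) -> float:
    """Two-pass sample standard deviation."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def brute_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r from explicit covariance / sigma-sigma."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def brute_singletons(calls: np.ndarray) -> int:
    """Count columns with exactly one derived entry by explicit tally."""
    n = 0
    for j in range(calls.shape[1]):
        carriers = sum(1 for i in range(calls.shape[0]) if calls[i, j] == 1)
        if carriers == 1:
            n += 1
    return n


def random_call_matrix(rng: np.random.Generator, n_samples: int, n_sites: int,
                       p_missing: float) -> np.ndarray:
    """A random {derived, ancestral, missing} matrix (no polymorphism filter)."""
    u = rng.random((n_samples, n_sites))
    out = np.where(u < p_missing, -1,
                   np.where(rng.random((n_samples, n_sites)) < 0.5, 1, 0))
    return out.astype(np.int8)
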