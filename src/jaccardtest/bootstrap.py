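"""Bootstrap empirical null for the centered Jaccard/Tanimoto coefficient.

Resampling each vector's elements with replacement, separately and
independently, destroys any dependence between the two species while
preserving their marginal occurrence frequencies.  The centered coefficient
of each resampled pair — with the expectation re-estimated from the
resampled vectors themselves, which avoids the bias of centering at an
expectation estimated once from the observed pair — forms an empirical null
distribution, and the two-sided empirical p-value is

    p = (1 + #{b : |stat_b| >= |observed|}) / (B + 1).

The pseudocount keeps p-values strictly positive, at the price of a slight
conservativeness of order 1/B.  B of at least 5-10 times m is recommended;
the default is B = 5 m.  For large screens, null statistics can be pooled
across pairs to increase p-value resolution beyond 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _states
from .core import (
    TestResult,
    VectorLike,
    as_binary_array,
    centered_from_quad,
    centered_values_from_counts,
    contingency,
)

__all__ = [
    "BootstrapNull",
    "bootstrap_null",
    "bootstrap_pvalue",
    "pooled_null_pvalues",
    "default_B",
]

#: Resample index blocks are drawn in chunks of at most this many entries to
#: bound peak memory for very long vectors.
_CHUNK_ENTRIES = 4_000_000


def default_B(m: int) -> int:
    """Recommended bootstrap iterations: 5 times the vector length."""
    return 5 * m


@dataclass
class BootstrapNull:
    """Empirical null statistics from B independent resampled pairs."""

    stats: np.ndarray
    B: int
    seed: Optional[int] = None
    pooled: bool = False


def _resampled_stats(
    a: np.ndarray, b: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Centered statistics of B pairs resampled with replacement.

    Draw order is fixed (per chunk: all indices for vector i, then for
    vector j) so a given seed reproduces the same statistics.
    """
    m = a.size
    out = np.empty(B, dtype=np.float64)
    step = max(1, _CHUNK_ENTRIES // m)
    for lo in range(0, B, step):
        nb = min(step, B - lo)
        ri = a[rng.integers(0, m, size=(nb, m))]
        rj = b[rng.integers(0, m, size=(nb, m))]
        n1 = np.einsum("ij,ij->i", ri, rj, dtype=np.int64)
        out[lo : lo + nb] = centered_values_from_counts(
            n1, ri.sum(axis=1, dtype=np.int64), rj.sum(axis=1, dtype=np.int64), m
        )
    return out


def bootstrap_null(
    y_i: VectorLike,
    y_j: VectorLike,
    B: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapNull:
    """Empirical null distribution of the centered coefficient.

    For each of B iterations, both vectors are independently resampled with
    replacement (m draws each) and the centered statistic is computed with
    the expectation estimated from the resampled vectors.  A resampled pair
    with an empty union takes the refined-coefficient convention: its
    coefficient equals its (resampled) expectation, hence statistic 0 —
    including the 0/0 case of two all-zero resamples.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    a = as_binary_array(y_i, "y_i")
    b = as_binary_array(y_j, "y_j")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if rng is None:
        rng = np.random.default_rng(seed)
    stats = _resampled_stats(a, b, B, rng)
    return BootstrapNull(stats=stats, B=B, seed=seed)


def _empirical_pvalue(null_stats: np.ndarray, observed: float) -> float:
    # same inclusive tie guard as the exact/MCA region test, so tied null
    # statistics are counted despite floating-point representation
    count = int(np.count_nonzero(np.abs(null_stats) >= abs(observed) - _states.TIE_GUARD))
    return (1.0 + count) / (null_stats.size + 1.0)


def bootstrap_pvalue(
    y_i: VectorLike,
    y_j: VectorLike,
    B: Optional[int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """Two-sided bootstrap p-value of the centered coefficient.

    ``B`` defaults to 5 m.  The p-value uses the pseudocount rule
    (1 + count) / (B + 1), so it is never exactly zero.
    """
    quad = contingency(y_i, y_j)
    result = centered_from_quad(quad)
    if B is None:
        B = default_B(quad.m)
    null = bootstrap_null(y_i, y_j, B, seed=seed, rng=rng)
    result.pvalue = _empirical_pvalue(null.stats, result.centered)
    result.method = "bootstrap"
    result.extras = {"B": B, "seed": seed}
    return result


def pooled_null_pvalues(
    pairs: Sequence[Tuple[VectorLike, VectorLike]],
    B_per_pair: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Bootstrap p-values with null statistics pooled across all pairs.

    Each pair contributes B_per_pair null statistics to a common pool, and
    every observed statistic is ranked against the full pool, giving a
    smallest achievable p-value of 1 / (n_pairs * B_per_pair + 1).  All
    pairs must share the same length m.  Resampling is pair-major (vector i
    before vector j within a pair) from a single generator, so a single
    pair reproduces :func:`bootstrap_pvalue` at the same seed.
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    rng = np.random.default_rng(seed)
    observed = np.empty(len(pairs))
    nulls = []
    m = None
    for k, (y_i, y_j) in enumerate(pairs):
        quad = contingency(y_i, y_j)
        if m is None:
            m = quad.m
        elif quad.m != m:
            raise ValueError("all pairs must share the same vector length")
        observed[k] = centered_from_quad(quad).centered
        nulls.append(bootstrap_null(y_i, y_j, B_per_pair, rng=rng).stats)
    pool = np.abs(np.concatenate(nulls))
    pool.sort()
    # count of pooled |stats| >= |obs| (tie-guarded) via binary search
    counts = pool.size - np.searchsorted(
        pool, np.abs(observed) - _states.TIE_GUARD, side="left"
    )
    return (1.0 + counts) / (pool.size + 1.0)
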