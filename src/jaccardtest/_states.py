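"""Shared multinomial state-space machinery for the exact and MCA engines.

The null distribution of the contingency counts (N1, N2, N3, N4) of a pair of
independent presence-absence vectors is multinomial with m trials.  Both the
exact test and the measure-concentration bounds are sums of the multinomial
pmf over states whose re-centered statistic is at least as extreme as the
observed one, so the per-state statistic and pmf evaluation live here.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Tuple

import numpy as np
from scipy.special import gammaln, xlogy

#: Absolute guard applied to the inclusive (>=) region comparison: a state
#: whose statistic falls within this amount below the observed threshold is
#: still counted, protecting exact ties from floating-point exclusion.
TIE_GUARD = 1e-12


@lru_cache(maxsize=4)
def state_table(m: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All quadruples (n1, n2, n3, m-n1-n2-n3) summing to m, plus statistics.

    Returns arrays ``(n1, n2, n3, stat)`` over the C(m+3, 3) states in
    lexicographic order of (n1, n2, n3), where ``stat`` is the per-state
    re-centered statistic of :func:`per_state_statistic`.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n1_parts, n2_parts, n3_parts = [], [], []
    for n1 in range(m + 1):
        r = m - n1
        n2 = np.repeat(np.arange(r + 1), np.arange(r + 1, 0, -1))
        n3 = np.concatenate([np.arange(r - k + 1) for k in range(r + 1)])
        n1_parts.append(np.full(n2.size, n1, dtype=np.int32))
        n2_parts.append(n2.astype(np.int32))
        n3_parts.append(n3.astype(np.int32))
    n1 = np.concatenate(n1_parts)
    n2 = np.concatenate(n2_parts)
    n3 = np.concatenate(n3_parts)
    stat = per_state_statistic(n1, n2, n3, m)
    for arr in (n1, n2, n3, stat):
        arr.setflags(write=False)
    return n1, n2, n3, stat


def n_states(m: int) -> int:
    """Number of multinomial states with 4 cells and m trials: C(m+3, 3)."""
    return (m + 1) * (m + 2) * (m + 3) // 6


def per_state_statistic(
    n1: np.ndarray, n2: np.ndarray, n3: np.ndarray, m: int
) -> np.ndarray:
    """Re-centered statistic of each state with its own probability estimates.

    For a state (N1, N2, N3, N4) the occurrence probabilities are estimated
    from that configuration itself, p~_i = (N1+N2)/m and p~_j = (N1+N3)/m,
    which de-biases the critical region relative to plugging in the observed
    sample's estimates.  The statistic is

        | N1/(N1+N2+N3) - p~_i p~_j / (p~_i + p~_j - p~_i p~_j) |.

    States with an empty union (N1+N2+N3 = 0) have both estimates zero and a
    0/0 expression; by the refined-coefficient convention their coefficient
    equals its expectation, so their statistic is defined as 0.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    n3 = np.asarray(n3, dtype=np.float64)
    union = n1 + n2 + n3
    p_i = (n1 + n2) / m
    p_j = (n1 + n3) / m
    denom = p_i + p_j - p_i * p_j
    with np.errstate(divide="ignore", invalid="ignore"):
        expectation = np.where(denom > 0, p_i * p_j / np.maximum(denom, 1e-300), 0.0)
        t = np.where(union > 0, n1 / np.maximum(union, 1.0), 0.0)
    return np.where(union > 0, np.abs(t - expectation), 0.0)


def known_p_statistic(
    n1: np.ndarray, n2: np.ndarray, n3: np.ndarray, expectation: float
) -> np.ndarray:
    """Per-state statistic |N1/(N1+N2+N3) - E| with a fixed known expectation.

    Empty-union states again have centered value 0 by the refined-coefficient
    convention (T equals the expectation there).
    """
    n1 = np.asarray(n1, dtype=np.float64)
    union = n1 + np.asarray(n2, dtype=np.float64) + np.asarray(n3, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(union > 0, n1 / np.maximum(union, 1.0), expectation)
    return np.where(union > 0, np.abs(t - expectation), 0.0)


def log_pmf(
    n1: np.ndarray,
    n2: np.ndarray,
    n3: np.ndarray,
    m: int,
    cell_probs: Tuple[float, float, float, float],
) -> np.ndarray:
    """Vectorised multinomial log-pmf over states, tolerant of zero cells."""
    gl = gammaln(np.arange(m + 2))
    n1 = np.asarray(n1)
    n2 = np.asarray(n2)
    n3 = np.asarray(n3)
    n4 = m - n1 - n2 - n3
    lp = gl[m + 1] - gl[n1 + 1] - gl[n2 + 1] - gl[n3 + 1] - gl[n4 + 1]
    for n, p in zip((n1, n2, n3, n4), cell_probs):
        if p > 0.0:
            lp = lp + xlogy(n, p)
        else:
            lp = np.where(n == 0, lp, -np.inf)
    return lp


def pmf(
    n1: np.ndarray,
    n2: np.ndarray,
    n3: np.ndarray,
    m: int,
    cell_probs: Tuple[float, float, float, float],
) -> np.ndarray:
    with np.errstate(over="ignore"):
        return np.exp(log_pmf(n1, n2, n3, m, cell_probs))
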