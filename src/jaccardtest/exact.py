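"""Exact p-values for the centered Jaccard/Tanimoto coefficient.

The exact two-sided p-value is the null mass of the critical region: the set
of multinomial states whose re-centered statistic is at least as extreme as
the observed one.  The full state space of (N1, N2, N3, N4) with
N1+N2+N3+N4 = m has C(m+3, 3) states, so the cost grows cubically in m; the
measure-concentration and bootstrap engines exist precisely to avoid this
enumeration for large m.

Two critical regions are supported:

* known occurrence probabilities — each state's statistic is its coefficient
  minus the fixed known expectation;
* estimated probabilities (the usual case) — plugging the observed sample's
  estimates into every state's statistic would bias the expectation toward
  the observed coefficient and make the test conservative, so each
  enumerated state re-estimates the probabilities from its own configuration
  (p~_i = (N1+N2)/m, p~_j = (N1+N3)/m).

In both cases the region is weighted by the multinomial pmf whose cell
probabilities come from the known (respectively observed plug-in) marginal
occurrence probabilities.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import _states
from .core import (
    ContingencyQuad,
    OccurrenceProbabilities,
    TestResult,
    VectorLike,
    centered_from_quad,
    contingency,
    expected_jaccard,
    jaccard_coefficient,
)

__all__ = [
    "StateEnumeration",
    "enumerate_states",
    "exact_pvalue",
    "exact_pvalue_known_p",
    "exact_pvalue_from_quad",
]

#: Refuse exhaustive enumeration above this vector length by default; the
#: O(m^3) state space makes the exact test impractically slow long before.
DEFAULT_MAX_M = 1000


class StateEnumeration:
    """The full multinomial state space for m trials over 4 cells.

    ``states`` is an (S, 4) integer array in lexicographic order of
    (n1, n2, n3); ``cell_probs``, when given, are the multinomial cell
    probabilities used to weight the states.
    """

    def __init__(self, m: int, cell_probs: Optional[tuple] = None):
        if m < 1:
            raise ValueError("m must be >= 1")
        self.m = m
        n1, n2, n3, stat = _states.state_table(m)
        self._n1, self._n2, self._n3 = n1, n2, n3
        self.statistic = stat
        self.cell_probs = None
        if cell_probs is not None:
            cp = tuple(float(p) for p in cell_probs)
            if abs(sum(cp) - 1.0) > 1e-9 or min(cp) < 0:
                raise ValueError("cell probabilities must be nonnegative and sum to 1")
            self.cell_probs = cp

    @property
    def states(self) -> np.ndarray:
        n4 = self.m - self._n1 - self._n2 - self._n3
        return np.column_stack([self._n1, self._n2, self._n3, n4])

    def __len__(self) -> int:
        return self._n1.size

    def pmf(self) -> np.ndarray:
        if self.cell_probs is None:
            raise ValueError("no cell probabilities attached to this enumeration")
        return _states.pmf(self._n1, self._n2, self._n3, self.m, self.cell_probs)


def enumerate_states(m: int) -> StateEnumeration:
    """Enumerate every quadruple (n1, n2, n3, n4) summing to m exactly once."""
    return StateEnumeration(m)


def _check_m(m: int, max_m: int) -> None:
    if m > max_m:
        raise ValueError(
            f"exact enumeration refused for m={m} > {max_m} "
            f"({_states.n_states(m)} states); use the measure-concentration "
            "or bootstrap engine instead, or raise max_m explicitly"
        )


def exact_pvalue_known_p(
    y_i: VectorLike,
    y_j: VectorLike,
    p_i: float,
    p_j: float,
    max_m: int = DEFAULT_MAX_M,
) -> TestResult:
    """Exact p-value when the occurrence probabilities are known.

    The observed statistic is T minus the known expectation
    ``p_i p_j / (p_i + p_j - p_i p_j)``; the critical region collects every
    state whose coefficient deviates from that same fixed expectation by at
    least |observed|, inclusively, weighted by the multinomial pmf with cells
    (p_i p_j, p_i(1-p_j), (1-p_i)p_j, (1-p_i)(1-p_j)).
    """
    if not (0.0 < p_i < 1.0 and 0.0 < p_j < 1.0):
        raise ValueError("known occurrence probabilities must lie strictly in (0, 1)")
    quad = contingency(y_i, y_j)
    _check_m(quad.m, max_m)
    probs = OccurrenceProbabilities(p_i, p_j, source="known")
    expectation = expected_jaccard(p_i, p_j)
    coefficient = jaccard_coefficient(quad, probs)
    centered = coefficient - expectation

    n1, n2, n3, _ = _states.state_table(quad.m)
    stat = _states.known_p_statistic(n1, n2, n3, expectation)
    mass = _states.pmf(n1, n2, n3, quad.m, probs.cell_probs)
    pvalue = float(mass[stat >= abs(centered) - _states.TIE_GUARD].sum())
    return TestResult(
        coefficient=coefficient,
        expectation=expectation,
        centered=centered,
        pvalue=min(pvalue, 1.0),
        method="exact",
        extras={"p_i": p_i, "p_j": p_j, "probabilities": "known"},
    )


def exact_pvalue_from_quad(
    quad: ContingencyQuad, max_m: int = DEFAULT_MAX_M
) -> TestResult:
    """Exact p-value with estimated probabilities, from contingency counts."""
    _check_m(quad.m, max_m)
    result = centered_from_quad(quad)  # raises on the all-zero/all-zero pair
    cell_probs = OccurrenceProbabilities.from_quad(quad).cell_probs

    n1, n2, n3, stat = _states.state_table(quad.m)
    mass = _states.pmf(n1, n2, n3, quad.m, cell_probs)
    pvalue = float(mass[stat >= abs(result.centered) - _states.TIE_GUARD].sum())
    result.pvalue = min(pvalue, 1.0)
    result.method = "exact"
    result.extras = {"probabilities": "estimated"}
    return result


def exact_pvalue(
    y_i: VectorLike, y_j: VectorLike, max_m: int = DEFAULT_MAX_M
) -> TestResult:
    """Exact p-value of the centered coefficient with estimated probabilities.

    The observed statistic uses plug-in estimates from the data; the critical
    region re-estimates the probabilities from each enumerated configuration
    separately (see module docstring), and is weighted by the multinomial
    pmf built from the observed plug-in estimates.
    """
    return exact_pvalue_from_quad(contingency(y_i, y_j), max_m=max_m)
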