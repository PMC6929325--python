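"""Core objects for Jaccard/Tanimoto similarity testing on presence-absence data.

A presence-absence vector records, for one species, whether it occurs (1) or
not (0) in each of ``m`` biogeographic units.  For a pair of such vectors the
similarity of their occurrence patterns is summarised by the Jaccard/Tanimoto
coefficient

    T = N1 / (N1 + N2 + N3),

where ``(N1, N2, N3, N4)`` count the units showing the patterns (1,1), (1,0),
(0,1) and (0,0) respectively.  Under independence, with occurrence
probabilities ``p_i`` and ``p_j``,

    E[T] = p_i * p_j / (p_i + p_j - p_i * p_j),

and the centered coefficient ``T_c = T - E[T]`` is the test statistic: its
sign encodes the direction of association, and the null hypothesis of
independence is ``T_c = 0``.

When both vectors are all zero the ratio ``N1/(N1+N2+N3)`` is undefined; the
refined definition of the coefficient assigns the expected value
``p_i p_j / (p_i + p_j - p_i p_j)`` in that case, so the centered value of an
empty-union pair is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np

__all__ = [
    "PresenceAbsenceVector",
    "ContingencyQuad",
    "OccurrenceProbabilities",
    "TestResult",
    "contingency",
    "jaccard_coefficient",
    "expected_jaccard",
    "centered_statistic",
]

VectorLike = Union["PresenceAbsenceVector", Sequence[int], np.ndarray]

#: Relative tolerance for the arithmetic identity centered == T - E[T].
CENTERING_RTOL = 1e-12


def as_binary_array(values: VectorLike, name: str = "vector") -> np.ndarray:
    """Coerce to a validated int8 array of 0/1 entries."""
    if isinstance(values, PresenceAbsenceVector):
        return values.values
    arr = np.asarray(values)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))][0]
        raise ValueError(f"{name} must contain only 0/1 entries, found {bad!r}")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class PresenceAbsenceVector:
    """Binary occurrence record of one species across ``m`` units."""

    values: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", as_binary_array(self.values, "values"))

    @property
    def m(self) -> int:
        return int(self.values.size)

    @property
    def occupancy(self) -> int:
        """Number of units where the species is present."""
        return int(self.values.sum())

    def __len__(self) -> int:
        return self.m


@dataclass(frozen=True)
class ContingencyQuad:
    """Cell counts (n1, n2, n3, n4) of the patterns (1,1), (1,0), (0,1), (0,0).

    Under independence the quadruple is multinomially distributed with m
    trials and cell probabilities (p_i p_j, p_i(1-p_j), (1-p_i)p_j,
    (1-p_i)(1-p_j)).
    """

    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def m(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    @property
    def union(self) -> int:
        """Units where at least one of the two species occurs."""
        return self.n1 + self.n2 + self.n3

    @property
    def p_hat_i(self) -> float:
        return (self.n1 + self.n2) / self.m

    @property
    def p_hat_j(self) -> float:
        return (self.n1 + self.n3) / self.m

    def swapped(self) -> "ContingencyQuad":
        return ContingencyQuad(self.n1, self.n3, self.n2, self.n4)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n1, self.n2, self.n3, self.n4)


@dataclass(frozen=True)
class OccurrenceProbabilities:
    """Marginal occurrence probabilities of a pair, with the derived q's.

    ``q1 = p_i p_j`` is the probability that both species occur in a unit;
    ``q2 = p_i + p_j - 2 p_i p_j`` that exactly one occurs.  ``source``
    records whether the probabilities are known, plug-in estimates from the
    observed pair, or per-configuration estimates used inside the exact
    critical region.
    """

    p_i: float
    p_j: float
    source: str = "known"

    def __post_init__(self) -> None:
        for name in ("p_i", "p_j"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
            object.__setattr__(self, name, v)
        if self.source not in ("known", "plugin_hat", "configuration_tilde"):
            raise ValueError(f"unknown source tag {self.source!r}")

    @property
    def q1(self) -> float:
        return self.p_i * self.p_j

    @property
    def q2(self) -> float:
        return self.p_i + self.p_j - 2.0 * self.p_i * self.p_j

    @property
    def cell_probs(self) -> tuple[float, float, float, float]:
        """Multinomial cell probabilities for (n1, n2, n3, n4)."""
        pi, pj = self.p_i, self.p_j
        return (pi * pj, pi * (1 - pj), (1 - pi) * pj, (1 - pi) * (1 - pj))

    @classmethod
    def from_quad(cls, quad: ContingencyQuad) -> "OccurrenceProbabilities":
        return cls(quad.p_hat_i, quad.p_hat_j, source="plugin_hat")


@dataclass
class TestResult:
    """Outcome of one similarity test.

    Attributes
    ----------
    coefficient
        The observed Jaccard/Tanimoto coefficient T.
    expectation
        E[T] under independence, from known or plug-in probabilities.
    centered
        T - E[T]; negative for avoidance, positive for co-occurrence.
    pvalue
        Two-sided p-value; ``None`` when only the statistic was computed.
    method
        One of ``exact``, ``asymptotic``, ``mca``, ``bootstrap``.
    extras
        Method-specific metadata (e.g. epsilon and the p-value bounds for
        the measure-concentration method; B and seed for the bootstrap).
    """

    __test__ = False  # keep pytest from collecting this as a test class

    coefficient: float
    expectation: float
    centered: float
    pvalue: Optional[float] = None
    method: Optional[str] = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scale = max(1.0, abs(self.coefficient), abs(self.expectation))
        if abs(self.centered - (self.coefficient - self.expectation)) > CENTERING_RTOL * scale:
            raise ValueError("centered must equal coefficient - expectation")
        if self.pvalue is not None and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue must lie in [0, 1], got {self.pvalue!r}")


def contingency(y_i: VectorLike, y_j: VectorLike) -> ContingencyQuad:
    """Reduce a pair of presence-absence vectors to its contingency counts.

    Symmetric under swapping the arguments up to the n2/n3 exchange.
    """
    a = as_binary_array(y_i, "y_i")
    b = as_binary_array(y_j, "y_j")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n1 = int(np.sum((a == 1) & (b == 1)))
    n2 = int(np.sum((a == 1) & (b == 0)))
    n3 = int(np.sum((a == 0) & (b == 1)))
    return ContingencyQuad(n1, n2, n3, a.size - n1 - n2 - n3)


def expected_jaccard(p_i: float, p_j: float) -> float:
    """Expected Jaccard/Tanimoto coefficient under independence.

    Returns ``p_i p_j / (p_i + p_j - p_i p_j)``, which is symmetric and
    monotone nondecreasing in each argument.  Undefined when both
    probabilities are zero.
    """
    if not (0.0 <= p_i <= 1.0 and 0.0 <= p_j <= 1.0):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    denom = p_i + p_j - p_i * p_j
    if denom == 0.0:
        raise ValueError("expectation undefined: both occurrence probabilities are zero")
    return p_i * p_j / denom


def jaccard_coefficient(
    quad: ContingencyQuad,
    probs: Optional[OccurrenceProbabilities] = None,
) -> float:
    """Refined Jaccard/Tanimoto coefficient of a contingency quadruple.

    Equals ``n1 / (n1 + n2 + n3)`` when the union is nonempty.  For an empty
    union the coefficient is defined as its expectation under independence,
    which requires ``probs``; with ``p_i = p_j = 0`` even the fallback is
    0/0 and an error is raised.
    """
    if quad.union > 0:
        return quad.n1 / quad.union
    if probs is None:
        raise ValueError(
            "coefficient undefined for an empty union without occurrence probabilities"
        )
    return expected_jaccard(probs.p_i, probs.p_j)


def centered_statistic(y_i: VectorLike, y_j: VectorLike) -> TestResult:
    """Centered Jaccard/Tanimoto coefficient with plug-in expectation.

    Estimates ``p_hat = (number of ones) / m`` from each vector, and returns
    T, E[T](p_hat_i, p_hat_j) and their difference.  The p-value field is
    left unset.  Raises for a pair of all-zero vectors, whose expectation is
    undefined.
    """
    quad = contingency(y_i, y_j)
    return centered_from_quad(quad)


def centered_from_quad(quad: ContingencyQuad) -> TestResult:
    """As :func:`centered_statistic`, starting from the contingency counts."""
    probs = OccurrenceProbabilities.from_quad(quad)
    if probs.p_i == 0.0 and probs.p_j == 0.0:
        raise ValueError(
            "degenerate input: both vectors are all zero, expectation undefined"
        )
    expectation = expected_jaccard(probs.p_i, probs.p_j)
    coefficient = jaccard_coefficient(quad, probs)
    return TestResult(
        coefficient=coefficient,
        expectation=expectation,
        centered=coefficient - expectation,
    )


def centered_values_from_counts(
    n1: np.ndarray, k_i: np.ndarray, k_j: np.ndarray, m: int
) -> np.ndarray:
    """Vectorised centered coefficients from intersection and marginal counts.

    ``k_i`` and ``k_j`` are the per-vector counts of ones.  Pairs with an
    empty union take the refined-coefficient convention T = E[T], i.e. a
    centered value of exactly zero (including the 0/0 case of two all-zero
    vectors, for which no deviation from independence is observable).
    """
    n1 = np.asarray(n1, dtype=np.float64)
    k_i = np.asarray(k_i, dtype=np.float64)
    k_j = np.asarray(k_j, dtype=np.float64)
    union = k_i + k_j - n1
    p_i, p_j = k_i / m, k_j / m
    denom = p_i + p_j - p_i * p_j
    with np.errstate(divide="ignore", invalid="ignore"):
        expectation = np.where(denom > 0, p_i * p_j / np.maximum(denom, 1e-300), 0.0)
        t = np.where(union > 0, n1 / np.maximum(union, 1.0), expectation)
    return t - expectation
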