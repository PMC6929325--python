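"""All-pairs co-occurrence screening on a presence-absence matrix.

Reads a species-by-units binary matrix, drops degenerate (constant) species,
tests every unordered pair of species with a chosen engine, and attaches
Storey q-values so discoveries can be called at a user-chosen false
discovery rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import bootstrap as _bootstrap
from . import mca as _mca
from .asymptotic import asymptotic_pvalue_from_quad
from .core import ContingencyQuad
from .exact import exact_pvalue_from_quad

__all__ = [
    "PresenceAbsenceMatrix",
    "PairwiseResults",
    "read_matrix",
    "filter_species",
    "pairwise_test",
    "qvalues",
    "METHODS",
]

METHODS = ("exact", "asymptotic", "mca", "bootstrap")

RESULT_COLUMNS = [
    "pair_a",
    "pair_b",
    "jaccard",
    "expectation",
    "centered",
    "pvalue",
    "qvalue",
    "method",
]


@dataclass
class PresenceAbsenceMatrix:
    """Binary occurrence matrix: one row per species, one column per unit."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size == 0:
            raise ValueError("matrix must have at least one species and one unit")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry {values[r, c]!r} at species "
                f"{self.data.index[r]!r}, unit {self.data.columns[c]!r}"
            )
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate species label {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate unit label {dup!r}")
        self.data = self.data.astype(np.int8)

    @property
    def species(self) -> list:
        return list(self.data.index)

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    def vector(self, label) -> np.ndarray:
        return self.data.loc[label].to_numpy()


@dataclass
class PairwiseResults:
    """Long-format table of all tested pairs, plus the pi0 estimate."""

    table: pd.DataFrame
    pi0: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def significant(self, qvalue_threshold: float) -> pd.DataFrame:
        return self.table[self.table["qvalue"] <= qvalue_threshold]


def read_matrix(
    path,
    orientation: str = "species_rows",
    sep: Optional[str] = None,
) -> PresenceAbsenceMatrix:
    """Read a delimited binary matrix with a header row and a label column.

    ``sep=None`` infers the delimiter from the extension (.csv gives a
    comma, anything else a tab).  ``orientation="species_columns"``
    transposes so species end up on the rows.
    """
    if orientation not in ("species_rows", "species_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "species_columns":
        df = df.T
    return PresenceAbsenceMatrix(df)


def filter_species(
    matrix: PresenceAbsenceMatrix, drop_constant: bool = True
) -> Tuple[PresenceAbsenceMatrix, pd.DataFrame]:
    """Drop species that are present everywhere or nowhere.

    A generalist present in every unit (or a species absent from all of
    them) has a degenerate occurrence probability estimate of 1 (or 0) and
    carries no co-occurrence information; the returned report lists each
    removal with its reason.
    """
    rows = []
    if drop_constant:
        sums = matrix.data.sum(axis=1)
        for label, s in sums.items():
            if s == matrix.m:
                rows.append((label, "present everywhere"))
            elif s == 0:
                rows.append((label, "absent everywhere"))
    report = pd.DataFrame(rows, columns=["species", "reason"])
    if len(report):
        kept = matrix.data.drop(index=report["species"].tolist())
        if kept.shape[0] == 0:
            import warnings

            warnings.warn("all species were constant; the filtered matrix is empty")
            return _EmptyMatrix(kept), report
        matrix = PresenceAbsenceMatrix(kept)
    return matrix, report


class _EmptyMatrix(PresenceAbsenceMatrix):
    """Degenerate filtered matrix with no species left; bypasses validation."""

    def __init__(self, data: pd.DataFrame):
        self.data = data


def _test_quad(quad: ContingencyQuad, method: str, epsilon: float, B, rng):
    if method == "exact":
        return exact_pvalue_from_quad(quad)
    if method == "asymptotic":
        return asymptotic_pvalue_from_quad(quad)
    if method == "mca":
        return _mca.mca_pvalue_from_quad(quad, epsilon=epsilon)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def pairwise_test(
    matrix: PresenceAbsenceMatrix,
    method: str = "mca",
    epsilon: float = _mca.DEFAULT_EPSILON,
    B: Optional[int] = None,
    seed: Optional[int] = None,
    pool_nulls: bool = False,
    pi0_method: str = "fixed",
) -> PairwiseResults:
    """Test every unordered pair of species and attach q-values.

    Records are ordered lexicographically by (pair_a, pair_b) with
    pair_a < pair_b, giving n(n-1)/2 rows.  The default engine is the
    measure-concentration algorithm; the bootstrap engine honours ``seed``
    and, with ``pool_nulls``, pools null statistics across all pairs.

    ``pi0_method`` defaults to the fixed-lambda Storey estimate: the
    engines' p-values have discrete supports (fully discrete for the
    enumeration-based engines, resolution 1/(B+1) for the bootstrap), which
    makes the lambda->1 smoother unstable; see :func:`qvalues`.
    """
    if matrix.n_species < 2:
        raise ValueError("need at least two species for a pairwise screen")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    labels = sorted(matrix.species, key=str)
    pairs = list(itertools.combinations(labels, 2))
    vecs = {lab: matrix.vector(lab) for lab in labels}

    records = []
    if method == "bootstrap":
        if B is None:
            B = _bootstrap.default_B(matrix.m)
        if pool_nulls:
            pvals = _bootstrap.pooled_null_pvalues(
                [(vecs[a], vecs[b]) for a, b in pairs], B, seed=seed
            )
        rng = np.random.default_rng(seed)
        for k, (a, b) in enumerate(pairs):
            try:
                if pool_nulls:
                    from .core import centered_statistic

                    res = centered_statistic(vecs[a], vecs[b])
                    res.pvalue = float(pvals[k])
                    res.method = "bootstrap"
                    res.extras = {"B": B, "seed": seed, "pooled": True}
                else:
                    res = _bootstrap.bootstrap_pvalue(vecs[a], vecs[b], B=B, rng=rng)
            except ValueError as err:
                raise ValueError(f"pair ({a!r}, {b!r}): {err}") from err
            records.append((a, b, res))
    else:
        rng = np.random.default_rng(seed)
        quads = _pair_quads(matrix, labels, pairs)
        for (a, b), quad in zip(pairs, quads):
            try:
                res = _test_quad(quad, method, epsilon, B, rng)
            except ValueError as err:
                raise ValueError(f"pair ({a!r}, {b!r}): {err}") from err
            records.append((a, b, res))

    table = pd.DataFrame(
        {
            "pair_a": [a for a, _, _ in records],
            "pair_b": [b for _, b, _ in records],
            "jaccard": [r.coefficient for _, _, r in records],
            "expectation": [r.expectation for _, _, r in records],
            "centered": [r.centered for _, _, r in records],
            "pvalue": [r.pvalue for _, _, r in records],
            "method": method,
        }
    )
    qv, pi0 = qvalues(table["pvalue"].to_numpy(), method=pi0_method)
    table["qvalue"] = qv
    table = table[RESULT_COLUMNS]
    meta = {"method": method, "seed": seed, "epsilon": epsilon, "B": B, "m": matrix.m}
    return PairwiseResults(table=table, pi0=pi0, metadata=meta)


def _pair_quads(matrix, labels, pairs):
    """Contingency quads for all pairs via one matrix product."""
    Y = matrix.data.loc[labels].to_numpy().astype(np.int64)
    inter = Y @ Y.T
    sums = Y.sum(axis=1)
    idx = {lab: k for k, lab in enumerate(labels)}
    out = []
    for a, b in pairs:
        i, j = idx[a], idx[b]
        n1 = int(inter[i, j])
        n2 = int(sums[i]) - n1
        n3 = int(sums[j]) - n1
        out.append(ContingencyQuad(n1, n2, n3, matrix.m - n1 - n2 - n3))
    return out


def qvalues(
    pvalues: Sequence[float],
    method: str = "smoother",
    lambdas: Optional[np.ndarray] = None,
    fixed_lambda: float = 0.5,
) -> Tuple[np.ndarray, float]:
    """Storey q-values and the pi0 estimate behind them.

    pi0, the proportion of truly null pairs, is estimated from the p-value
    histogram above a grid of lambda cutoffs, pi0(lambda) =
    #{p > lambda} / (n (1 - lambda)), extrapolated to lambda -> 1 with a
    cubic smoother and clipped to (0, 1].  With ``method="fixed"`` the
    single-cutoff estimate pi0(fixed_lambda) is used instead — more stable
    when the p-value support is discrete, as with the exact engine at small
    m.  Q-values are the monotone step-up transform of the pi0-scaled FDR:
    q_(i) = min over j >= i of pi0 * n * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("pvalues must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("pvalues must lie in [0, 1]")

    if method == "smoother":
        if lambdas is None:
            lambdas = np.arange(0.0, 0.95, 0.05)
        lambdas = np.asarray(lambdas, dtype=np.float64)
        pi0_grid = np.array(
            [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
        )
        if lambdas.size >= 4:
            coeffs = np.polyfit(lambdas, pi0_grid, deg=3)
            pi0 = float(np.polyval(coeffs, lambdas.max()))
        else:
            pi0 = float(pi0_grid[-1])
    elif method == "fixed":
        pi0 = float(np.mean(p > fixed_lambda) / (1.0 - fixed_lambda))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    pi0 = float(np.clip(pi0, 1.0 / p.size, 1.0))

    order = np.argsort(p, kind="mergesort")
    n = p.size
    ranked = pi0 * n * p[order] / np.arange(1, n + 1)
    qv_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qv_sorted = np.minimum(qv_sorted, 1.0)
    qv = np.empty(n)
    qv[order] = qv_sorted
    return qv, pi0
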