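"""Synthetic presence-absence data and calibration/FDR/runtime studies.

Null data are i.i.d. Bernoulli(p) vectors: two independent species observed
across m units.  Dependent pairs, used in the false-discovery studies, are
generated by copying the query vector elementwise with probability rho and
drawing a fresh Bernoulli(p) entry otherwise — a mechanism that spans
independence (rho = 0) to identity (rho = 1) while preserving the marginal
occurrence probability p.

Three study harnesses mirror the standard evaluation designs for this kind
of test:

* null calibration — p-values of many independent pairs, which should be
  Uniform(0, 1); summarised by a Kolmogorov-Smirnov statistic per method;
* FDR study — a mixture of null and dependent pairs with a known null
  proportion pi0; q-value thresholds are compared against the observed
  false discovery proportion, computable exactly from the ground truth;
* timing comparison — wall-clock per method over a grid of vector lengths
  (informational only; absolute timings are hardware-dependent).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import kstest

from . import bootstrap as _bootstrap
from . import mca as _mca
from .asymptotic import asymptotic_pvalue_from_quad
from .core import ContingencyQuad
from .exact import exact_pvalue_from_quad
from .pipeline import qvalues

__all__ = [
    "SimulationDesign",
    "simulate_null_pairs",
    "simulate_mixture",
    "run_null_calibration",
    "run_fdr_study",
    "run_timing_comparison",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic study.

    n: number of companion vectors (or pairs); m: vector length;
    p: occurrence probability; pi0: proportion of truly independent
    companions; rho: dependence strength of the non-null companions;
    replicates: independent repetitions of the whole scenario.
    """

    n: int = 2000
    m: int = 100
    p: float = 0.5
    pi0: float = 1.0
    rho: float = 0.5
    seed: Optional[int] = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1 or self.replicates < 1:
            raise ValueError("n, m and replicates must be positive")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly in (0, 1)")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_null_pairs(
    n_pairs: int, m: int, p: float, seed=None
) -> Tuple[np.ndarray, np.ndarray]:
    """Mutually independent pairs of i.i.d. Bernoulli(p) vectors.

    Returns two (n_pairs, m) binary arrays; row k of each forms pair k.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    rng = _rng(seed)
    yi = (rng.random((n_pairs, m)) < p).astype(np.int8)
    yj = (rng.random((n_pairs, m)) < p).astype(np.int8)
    return yi, yj


def simulate_mixture(
    design: SimulationDesign, seed=None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A query vector, n companions, and ground-truth association labels.

    ceil(pi0 * n) companions are independent Bernoulli(p) vectors; the rest
    copy the query elementwise with probability rho (fresh Bernoulli(p)
    otherwise).  Returns (query, companions, truth) where truth[k] is True
    for the truly associated companions.
    """
    rng = _rng(seed if seed is not None else design.seed)
    n, m, p, rho = design.n, design.m, design.p, design.rho
    query = (rng.random(m) < p).astype(np.int8)
    n_null = math.ceil(design.pi0 * n)
    n_alt = n - n_null
    companions = np.empty((n, m), dtype=np.int8)
    companions[:n_null] = (rng.random((n_null, m)) < p).astype(np.int8)
    if n_alt:
        fresh = (rng.random((n_alt, m)) < p).astype(np.int8)
        copy_mask = rng.random((n_alt, m)) < rho
        companions[n_null:] = np.where(copy_mask, query[None, :], fresh)
    truth = np.zeros(n, dtype=bool)
    truth[n_null:] = True
    return query, companions, truth


def _pvalue_from_quad(quad, method, epsilon, B, rng):
    if method == "exact":
        return exact_pvalue_from_quad(quad).pvalue
    if method == "asymptotic":
        return asymptotic_pvalue_from_quad(quad).pvalue
    if method == "mca":
        return _mca.mca_pvalue_from_quad(quad, epsilon=epsilon).pvalue
    raise ValueError(f"unknown method {method!r}")


def _quads_from_rows(yi: np.ndarray, yj: np.ndarray) -> list:
    n1 = np.einsum("ij,ij->i", yi.astype(np.int64), yj.astype(np.int64))
    ki = yi.sum(axis=1, dtype=np.int64)
    kj = yj.sum(axis=1, dtype=np.int64)
    m = yi.shape[1]
    return [
        ContingencyQuad(int(a), int(b - a), int(c - a), int(m - b - c + a))
        for a, b, c in zip(n1, ki, kj)
    ]


def _pvalues_for_pairs(
    yi: np.ndarray,
    yj: np.ndarray,
    method: str,
    B: Optional[int],
    epsilon: float,
    rng: np.random.Generator,
) -> np.ndarray:
    m = yi.shape[1]
    if method == "bootstrap":
        b = B if B is not None else _bootstrap.default_B(m)
        return np.array(
            [
                _bootstrap.bootstrap_pvalue(a, c, B=b, rng=rng).pvalue
                for a, c in zip(yi, yj)
            ]
        )
    quads = _quads_from_rows(yi, yj)
    return np.array([_pvalue_from_quad(q, method, epsilon, B, rng) for q in quads])


def run_null_calibration(
    m: int = 100,
    p: float = 0.5,
    n_pairs: int = 2000,
    methods: Sequence[str] = ("exact", "asymptotic", "mca", "bootstrap"),
    B: Optional[int] = 500,
    epsilon: float = _mca.DEFAULT_EPSILON,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """P-values of independent pairs, per method, with uniformity diagnostics.

    Returns ``(pvalues, diagnostics)``: a table with one p-value column per
    method, and per-method Kolmogorov-Smirnov statistics against
    Uniform(0, 1).  All methods are applied to the same simulated pairs.
    """
    rng = _rng(seed)
    yi, yj = simulate_null_pairs(n_pairs, m, p, seed=rng)
    pvals = {}
    for method in methods:
        pvals[method] = _pvalues_for_pairs(yi, yj, method, B, epsilon, rng)
    pvalues = pd.DataFrame(pvals)
    rows = []
    for method in methods:
        ks = kstest(pvalues[method], "uniform")
        rows.append((method, ks.statistic, ks.pvalue))
    diagnostics = pd.DataFrame(rows, columns=["method", "ks_statistic", "ks_pvalue"])
    return pvalues, diagnostics


def run_fdr_study(
    design: SimulationDesign,
    methods: Sequence[str] = ("asymptotic", "mca", "bootstrap"),
    thresholds: Optional[np.ndarray] = None,
    B: Optional[int] = None,
    epsilon: float = _mca.DEFAULT_EPSILON,
    pi0_method: str = "fixed",
) -> pd.DataFrame:
    """Observed false discovery proportion against the q-value threshold.

    For each replicate a mixture with known truth is generated; every
    companion is tested against the query, p-values are converted to
    q-values, and the observed FDP (false discoveries / discoveries, 0 when
    nothing is discovered) is recorded at each threshold.  Returns a long
    table (method, pi0, replicate, threshold, fdp, discoveries,
    true_positives) — averaging fdp over replicates per threshold gives the
    calibration curve.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.21, 0.01), 2)
    master = np.random.default_rng(design.seed)
    rows = []
    for rep in range(design.replicates):
        rep_rng = np.random.default_rng(master.integers(2**31))
        query, companions, truth = simulate_mixture(design, seed=rep_rng)
        yi = np.broadcast_to(query, companions.shape)
        for method in methods:
            pv = _pvalues_for_pairs(yi, companions, method, B, epsilon, rep_rng)
            qv, _ = qvalues(pv, method=pi0_method)
            for t in thresholds:
                called = qv <= t
                disc = int(called.sum())
                false = int((called & ~truth).sum())
                fdp = false / disc if disc else 0.0
                rows.append((method, design.pi0, rep, float(t), fdp, disc, disc - false))
    return pd.DataFrame(
        rows,
        columns=[
            "method",
            "pi0",
            "replicate",
            "threshold",
            "fdp",
            "discoveries",
            "true_positives",
        ],
    )


def run_timing_comparison(
    m_grid: Iterable[int] = (50, 100, 200),
    methods: Sequence[str] = ("exact", "asymptotic", "mca", "bootstrap"),
    repeats: int = 3,
    p: float = 0.5,
    epsilon: float = _mca.DEFAULT_EPSILON,
    seed: Optional[int] = None,
    exact_max_m: int = 1000,
) -> pd.DataFrame:
    """Mean wall-clock seconds per test, per method and vector length.

    Informational only — timings depend on hardware.  The expected ordinal
    relation at large m is exact slowest and asymptotic fastest, with the
    bootstrap and measure-concentration engines in between.  An exact run
    refused by the enumeration cap is recorded as not run (NaN).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = _rng(seed)
    rows = []
    for m in m_grid:
        yi, yj = simulate_null_pairs(repeats, m, p, seed=rng)
        for method in methods:
            total, ran = 0.0, 0
            # fresh caches so MCA timings include set construction
            _mca._SET_CACHE.clear()
            for k in range(repeats):
                t0 = time.perf_counter()
                try:
                    if method == "exact":
                        exact_pvalue_from_quad(
                            _quads_from_rows(yi[k : k + 1], yj[k : k + 1])[0],
                            max_m=exact_max_m,
                        )
                    else:
                        _pvalues_for_pairs(
                            yi[k : k + 1], yj[k : k + 1], method, None, epsilon, rng
                        )
                except ValueError:
                    break
                total += time.perf_counter() - t0
                ran += 1
            rows.append((m, method, total / ran if ran else np.nan, ran))
    return pd.DataFrame(rows, columns=["m", "method", "seconds", "runs"])
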