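"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's multinomial state-space machinery:
they enumerate the full space of binary vector pairs and weight each pair by
its Bernoulli probability, so agreement with the package is a genuine
cross-check of the enumeration engines, not a tautology.  Only feasible for
small m (the vector space has 4^m pairs).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

GUARD = 1e-12


def config_statistic(n1: int, n2: int, n3: int, m: int) -> float:
    """Re-centered statistic of one configuration with its own estimates."""
    s = n1 + n2 + n3
    if s == 0:
        return 0.0
    pi = (n1 + n2) / m
    pj = (n1 + n3) / m
    return abs(n1 / s - pi * pj / (pi + pj - pi * pj))


def observed_centered(n1: int, n2: int, n3: int, m: int) -> float:
    """Observed centered coefficient of a pair with the given counts."""
    pi = (n1 + n2) / m
    pj = (n1 + n3) / m
    e = pi * pj / (pi + pj - pi * pj) if pi + pj > 0 else 0.0
    s = n1 + n2 + n3
    t = n1 / s if s else e
    return t - e


def all_vectors(m: int) -> np.ndarray:
    """All 2^m binary vectors as a (2^m, m) array."""
    return np.array(list(itertools.product((0, 1), repeat=m)), dtype=np.int8)


def brute_force_pvalue(n1: int, n2: int, n3: int, m: int) -> float:
    """Exact p-value by summing over all 4^m Bernoulli-weighted vector pairs.

    Weights use the observed pair's plug-in probability estimates; each
    enumerated pair's statistic re-estimates the probabilities from its own
    counts.  Equals the multinomial-region p-value by construction.
    """
    pi = (n1 + n2) / m
    pj = (n1 + n3) / m
    thr = abs(observed_centered(n1, n2, n3, m)) - GUARD
    total = 0.0
    for u in itertools.product((0, 1), repeat=m):
        su = sum(u)
        wu = pi**su * (1 - pi) ** (m - su)
        if wu == 0.0:
            continue
        for v in itertools.product((0, 1), repeat=m):
            sv = sum(v)
            wv = pj**sv * (1 - pj) ** (m - sv)
            if wv == 0.0:
                continue
            k1 = sum(a & b for a, b in zip(u, v))
            if config_statistic(k1, su - k1, sv - k1, m) >= thr:
                total += wu * wv
    return total


def brute_force_pvalue_known(
    n1: int, n2: int, n3: int, m: int, p_i: float, p_j: float
) -> float:
    """As above but with known probabilities and a fixed expectation."""
    e = p_i * p_j / (p_i + p_j - p_i * p_j)
    s = n1 + n2 + n3
    t = n1 / s if s else e
    thr = abs(t - e) - GUARD
    total = 0.0
    for u in itertools.product((0, 1), repeat=m):
        su = sum(u)
        wu = p_i**su * (1 - p_i) ** (m - su)
        for v in itertools.product((0, 1), repeat=m):
            sv = sum(v)
            wv = p_j**sv * (1 - p_j) ** (m - sv)
            k1 = sum(a & b for a, b in zip(u, v))
            ks = su + sv - k1
            tk = k1 / ks if ks else e
            if abs(tk - e) >= thr:
                total += wu * wv
    return total


def brute_force_expected_T(m: int, p_i: float, p_j: float) -> float:
    """E[T] by exhaustive enumeration of all weighted vector pairs."""
    e_fallback = p_i * p_j / (p_i + p_j - p_i * p_j)
    total = 0.0
    for u in itertools.product((0, 1), repeat=m):
        su = sum(u)
        wu = p_i**su * (1 - p_i) ** (m - su)
        for v in itertools.product((0, 1), repeat=m):
            sv = sum(v)
            wv = p_j**sv * (1 - p_j) ** (m - sv)
            k1 = sum(a & b for a, b in zip(u, v))
            ks = su + sv - k1
            t = k1 / ks if ks else e_fallback
            total += wu * wv * t
    return total


def bucketed_brute_pvalues(m: int):
    """Brute-force p-values of every attainable configuration at length m.

    Vectorised version of :func:`brute_force_pvalue` for sweeping all
    configurations at once: enumerates the 4^m vector pairs a single time,
    buckets their Bernoulli weights by configuration for each distinct pair
    of plug-in probability estimates, then sums buckets over each observed
    configuration's critical region.  Returns ``{(n1, n2, n3): pvalue}`` for
    all configurations except the all-absent one.
    """
    V = all_vectors(m)
    n_vec = V.shape[0]
    sums = V.sum(axis=1)
    inter = (V @ V.T).astype(np.int64)
    su = np.broadcast_to(sums[:, None], inter.shape)
    sv = np.broadcast_to(sums[None, :], inter.shape)
    # encode each (n1, su, sv) configuration as one bucket id
    code = (inter * (m + 1) + su) * (m + 1) + sv
    code_flat = code.ravel()
    n_codes = (m + 1) ** 3

    def safe_stat(k1, a, b):
        # invalid (k1, a, b) combinations never receive weight; value arbitrary
        if k1 > min(a, b) or a + b - k1 > m:
            return 0.0
        return config_statistic(k1, a - k1, b - k1, m)

    stat = np.array(
        [
            safe_stat(k1, a, b)
            for k1 in range(m + 1)
            for a in range(m + 1)
            for b in range(m + 1)
        ]
    )  # indexed by code

    # bucket weights for every distinct (p_hat_i, p_hat_j) = (a/m, b/m)
    pow_table = {}
    for a in range(m + 1):
        p = a / m
        pow_table[a] = p ** sums * (1 - p) ** (m - sums)

    out = {}
    bucket_cache = {}
    for k1 in range(m + 1):
        for n2 in range(m + 1 - k1):
            for n3 in range(m + 1 - k1 - n2):
                a, b = k1 + n2, k1 + n3
                if a == 0 and b == 0:
                    continue  # all-absent pair: statistic undefined
                key = (a, b)
                if key not in bucket_cache:
                    w = np.outer(pow_table[a], pow_table[b]).ravel()
                    bucket_cache[key] = np.bincount(
                        code_flat, weights=w, minlength=n_codes
                    )
                thr = abs(observed_centered(k1, n2, n3, m)) - GUARD
                out[(k1, n2, n3)] = float(bucket_cache[key][stat >= thr].sum())
    return out
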