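"""Coefficient, expectation and centered-statistic arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jaccardtest.core import (
    ContingencyQuad,
    OccurrenceProbabilities,
    TestResult,
    centered_statistic,
    contingency,
    expected_jaccard,
    jaccard_coefficient,
)

from helpers_oracle import brute_force_expected_T

binary_vectors = st.lists(st.integers(0, 1), min_size=1, max_size=30)


class TestContingency:
    @pytest.mark.parametrize(
        "y_i, y_j, expected",
        [
            ((1, 1, 0, 0), (1, 0, 1, 0), (1, 1, 1, 1)),
            ((1, 1, 1, 0, 0), (1, 1, 1, 0, 0), (3, 0, 0, 2)),
            ((0, 0, 0, 0, 0), (0, 0, 0, 0, 0), (0, 0, 0, 5)),
        ],
    )
    def test_counts(self, y_i, y_j, expected):
        quad = contingency(y_i, y_j)
        assert quad.as_tuple() == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            contingency([1, 0], [1, 0, 1])

    def test_non_binary_entry(self):
        with pytest.raises(ValueError, match="0/1"):
            contingency([1, 2, 0], [1, 0, 0])

    @given(y_i=binary_vectors, y_j=binary_vectors)
    @settings(max_examples=60, deadline=None)
    def test_swap_symmetry_and_conservation(self, y_i, y_j):
        if len(y_i) != len(y_j):
            y_j = (y_j * (len(y_i) // len(y_j) + 1))[: len(y_i)]
        quad = contingency(y_i, y_j)
        assert quad.m == len(y_i)
        assert contingency(y_j, y_i).as_tuple() == quad.swapped().as_tuple()

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyQuad(-1, 0, 0, 3)


class TestJaccardCoefficient:
    def test_basic_ratio(self):
        assert jaccard_coefficient(ContingencyQuad(1, 1, 1, 1)) == pytest.approx(1 / 3)

    def test_identical_vectors(self):
        assert jaccard_coefficient(ContingencyQuad(3, 0, 0, 2)) == 1.0

    def test_empty_union_fallback(self):
        probs = OccurrenceProbabilities(0.5, 0.5)
        assert jaccard_coefficient(ContingencyQuad(0, 0, 0, 5), probs) == pytest.approx(1 / 3)

    def test_empty_union_without_probs(self):
        with pytest.raises(ValueError, match="undefined"):
            jaccard_coefficient(ContingencyQuad(0, 0, 0, 5))

    def test_empty_union_zero_probs(self):
        with pytest.raises(ValueError):
            jaccard_coefficient(ContingencyQuad(0, 0, 0, 5), OccurrenceProbabilities(0.0, 0.0))

    @given(y_i=binary_vectors)
    @settings(max_examples=40, deadline=None)
    def test_bounds(self, y_i):
        rng = np.random.default_rng(len(y_i))
        y_j = rng.integers(0, 2, len(y_i))
        quad = contingency(y_i, y_j)
        if quad.union:
            assert 0.0 <= jaccard_coefficient(quad) <= 1.0


class TestExpectedJaccard:
    @pytest.mark.parametrize(
        "p_i, p_j, expected",
        [(0.5, 0.5, 1 / 3), (1.0, 1.0, 1.0), (0.0, 0.7, 0.0)],
    )
    def test_values(self, p_i, p_j, expected):
        assert expected_jaccard(p_i, p_j) == pytest.approx(expected)

    def test_undefined_at_origin(self):
        with pytest.raises(ValueError, match="undefined"):
            expected_jaccard(0.0, 0.0)

    @given(
        p_i=st.floats(0.01, 1.0),
        p_j=st.floats(0.01, 1.0),
        delta=st.floats(0.0, 0.5),
    )
    @settings(max_examples=80, deadline=None)
    def test_symmetry_and_monotonicity(self, p_i, p_j, delta):
        e = expected_jaccard(p_i, p_j)
        assert e == pytest.approx(expected_jaccard(p_j, p_i))
        assert expected_jaccard(min(p_i + delta, 1.0), p_j) >= e - 1e-12

    @given(p=st.floats(0.01, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_equal_probability_identity(self, p):
        assert expected_jaccard(p, p) == pytest.approx(p / (2 - p))

    @pytest.mark.parametrize(
        "m, p_i, p_j", [(4, 0.5, 0.5), (5, 0.3, 0.6), (5, 0.9, 0.2)]
    )
    def test_matches_exhaustive_enumeration(self, m, p_i, p_j):
        """E[T] from summing T over all weighted vector pairs equals the closed form."""
        brute = brute_force_expected_T(m, p_i, p_j)
        assert brute == pytest.approx(expected_jaccard(p_i, p_j), abs=1e-12)

    def test_monte_carlo_mean(self, rng):
        """The closed form matches a simulation average within 3 standard errors."""
        n, m, p_i, p_j = 20000, 100, 0.3, 0.6
        yi = (rng.random((n, m)) < p_i).astype(np.int8)
        yj = (rng.random((n, m)) < p_j).astype(np.int8)
        n1 = np.einsum("ij,ij->i", yi, yj, dtype=np.int64)
        union = yi.sum(1, dtype=np.int64) + yj.sum(1, dtype=np.int64) - n1
        t = n1 / union  # union is never 0 at these parameters and m
        se = t.std(ddof=1) / np.sqrt(n)
        assert abs(t.mean() - expected_jaccard(p_i, p_j)) < 3 * se


class TestCenteredStatistic:
    def test_identical_nonconstant(self):
        res = centered_statistic([1, 1, 0, 0], [1, 1, 0, 0])
        assert res.coefficient == 1.0
        assert res.expectation == pytest.approx(1 / 3)
        assert res.centered == pytest.approx(2 / 3)
        assert res.pvalue is None

    def test_disjoint_negative(self):
        res = centered_statistic([1, 1, 0, 0], [0, 0, 1, 1])
        assert res.coefficient == 0.0
        assert res.centered == pytest.approx(-1 / 3)

    @given(y_i=binary_vectors, y_j=binary_vectors)
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_range(self, y_i, y_j):
        if len(y_i) != len(y_j):
            y_j = (y_j * (len(y_i) // len(y_j) + 1))[: len(y_i)]
        if sum(y_i) == 0 and sum(y_j) == 0:
            return
        a = centered_statistic(y_i, y_j)
        b = centered_statistic(y_j, y_i)
        assert a.centered == pytest.approx(b.centered)
        assert -1.0 <= a.centered <= 1.0

    def test_all_zero_pair_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            centered_statistic([0, 0, 0], [0, 0, 0])


class TestResultValidation:
    def test_inconsistent_centering_rejected(self):
        with pytest.raises(ValueError, match="centered"):
            TestResult(coefficient=0.5, expectation=0.3, centered=0.1)

    def test_pvalue_range_enforced(self):
        with pytest.raises(ValueError, match="pvalue"):
            TestResult(coefficient=0.5, expectation=0.3, centered=0.2, pvalue=1.5)
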