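"""Exact multinomial p-values against independent brute-force oracles."""

import numpy as np
import pytest

from jaccardtest import _states
from jaccardtest.core import ContingencyQuad
from jaccardtest.exact import (
    enumerate_states,
    exact_pvalue,
    exact_pvalue_from_quad,
    exact_pvalue_known_p,
)

from conftest import random_pair
from helpers_oracle import brute_force_pvalue, brute_force_pvalue_known


class TestEnumeration:
    @pytest.mark.parametrize("m, expected", [(1, 4), (2, 10), (10, 286)])
    def test_state_counts(self, m, expected):
        enum = enumerate_states(m)
        assert len(enum) == expected
        states = enum.states
        assert states.shape == (expected, 4)
        assert (states.sum(axis=1) == m).all()
        # each quadruple appears exactly once
        assert len({tuple(s) for s in states}) == expected

    @pytest.mark.parametrize("probs", [(0.25, 0.25, 0.25, 0.25), (0.06, 0.24, 0.14, 0.56)])
    def test_pmf_sums_to_one(self, probs):
        enum = enumerate_states(12)
        mass = _states.pmf(enum.states[:, 0], enum.states[:, 1], enum.states[:, 2], 12, probs)
        assert mass.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            enumerate_states(0)


class TestKnownProbabilities:
    def test_matches_vector_space_oracle(self):
        res = exact_pvalue_known_p([1, 1, 0], [1, 0, 1], 0.5, 0.5)
        brute = brute_force_pvalue_known(1, 1, 1, 3, 0.5, 0.5)
        assert res.pvalue == pytest.approx(brute, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 6))
        y_i, y_j = random_pair(rng, m)
        p_i, p_j = rng.uniform(0.2, 0.8, 2)
        quad_n1 = int(np.sum((y_i == 1) & (y_j == 1)))
        n2 = int(y_i.sum()) - quad_n1
        n3 = int(y_j.sum()) - quad_n1
        res = exact_pvalue_known_p(y_i, y_j, p_i, p_j)
        brute = brute_force_pvalue_known(quad_n1, n2, n3, m, p_i, p_j)
        assert res.pvalue == pytest.approx(brute, abs=1e-10)

    def test_swap_symmetry(self, rng):
        y_i, y_j = random_pair(rng, 8)
        a = exact_pvalue_known_p(y_i, y_j, 0.4, 0.7)
        b = exact_pvalue_known_p(y_j, y_i, 0.7, 0.4)
        assert a.pvalue == pytest.approx(b.pvalue, abs=1e-12)

    def test_zero_statistic_gives_pvalue_one(self):
        # T = 1/3 equals the expectation at p_i = p_j = 0.5
        res = exact_pvalue_known_p([1, 1, 0, 0], [1, 0, 1, 0], 0.5, 0.5)
        assert res.centered == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("p_i, p_j", [(0.0, 0.5), (1.0, 0.5), (0.5, 1.0)])
    def test_degenerate_probability_rejected(self, p_i, p_j):
        with pytest.raises(ValueError, match="strictly"):
            exact_pvalue_known_p([1, 0], [0, 1], p_i, p_j)


class TestEstimatedProbabilities:
    def test_spec_instance_matches_oracle(self):
        y_i = [1, 1, 1, 0, 0]
        y_j = [1, 1, 0, 1, 0]
        res = exact_pvalue(y_i, y_j)
        brute = brute_force_pvalue(2, 1, 1, 5)
        assert res.pvalue == pytest.approx(brute, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = int(rng.integers(2, 7))
        y_i, y_j = random_pair(rng, m)
        n1 = int(np.sum((y_i == 1) & (y_j == 1)))
        n2 = int(y_i.sum()) - n1
        n3 = int(y_j.sum()) - n1
        assert exact_pvalue(y_i, y_j).pvalue == pytest.approx(
            brute_force_pvalue(n1, n2, n3, m), abs=1e-10
        )

    def test_zero_statistic_gives_pvalue_one(self):
        res = exact_pvalue([1, 1, 0, 0], [1, 0, 1, 0])  # T = E = 1/3
        assert res.centered == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_swap_symmetry(self, rng):
        y_i, y_j = random_pair(rng, 12)
        assert exact_pvalue(y_i, y_j).pvalue == pytest.approx(
            exact_pvalue(y_j, y_i).pvalue, abs=1e-12
        )

    def test_monotone_in_observed_statistic(self):
        """With m and the marginals fixed, a larger |statistic| can only shrink p."""
        m, a, b = 30, 12, 15
        rows = []
        for n1 in range(max(0, a + b - m), min(a, b) + 1):
            quad = ContingencyQuad(n1, a - n1, b - n1, m - a - b + n1)
            res = exact_pvalue_from_quad(quad)
            rows.append((abs(res.centered), res.pvalue))
        rows.sort()
        pvals = [p for _, p in rows]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(pvals, pvals[1:]))

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            exact_pvalue([0, 0, 0], [0, 0, 0])

    def test_single_all_zero_vector_is_uninformative(self):
        res = exact_pvalue([0, 0, 0, 0], [0, 1, 1, 0])
        assert res.centered == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_complexity_guard(self):
        y = np.tile([1, 0], 600)
        with pytest.raises(ValueError, match="bootstrap"):
            exact_pvalue(y, y[::-1], max_m=1000)
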