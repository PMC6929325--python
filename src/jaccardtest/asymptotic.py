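"""Large-m normal approximation of the centered coefficient's null law.

Writing q1 = p_i p_j for the probability that both species occupy a unit and
q2 = p_i + p_j - 2 p_i p_j for the probability that exactly one does, the
central limit theorem for the multinomial counts together with the delta
method applied to g(x1, x2) = x1/(x1 + x2) gives

    sqrt(m) * T_c  ->  N(0, sigma^2),    sigma^2 = q1 q2 / (q1 + q2)^3,

since with Sigma = [[q1(1-q1), -q1 q2], [-q1 q2, q2(1-q2)]] and
grad g = (q2, -q1)/(q1+q2)^2 the quadratic form collapses to
q1 q2 (q1+q2) / (q1+q2)^4.  (A variant of this variance carrying an extra
(1-q2) factor circulates; it does not satisfy the delta-method identity and
under-states the variance, inflating |z| by 1/sqrt(1-q2) — permanently, not
vanishing with m.  Simulation confirms the form used here.)

The two-sided p-value is 2 * (1 - Phi(|z|)) with z = sqrt(m) * T_c / sigma,
using plug-in estimates of q1 and q2.  This is still a large-m device: at
moderate m the discrete, skewed null of T_c makes the normal tails
inaccurate, so the pairwise pipeline defaults to the measure-concentration
engine and this method is recommended only when runtime is the binding
constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .core import (
    TestResult,
    VectorLike,
    ContingencyQuad,
    OccurrenceProbabilities,
    centered_from_quad,
    contingency,
)

__all__ = ["AsymptoticVariance", "asymptotic_variance", "asymptotic_pvalue"]


@dataclass(frozen=True)
class AsymptoticVariance:
    """Limiting variance of sqrt(m) * T_c and the probabilities behind it."""

    sigma2: float
    q1: float
    q2: float


def asymptotic_variance(q1: float, q2: float) -> AsymptoticVariance:
    """Delta-method variance q1 q2 / (q1+q2)^3 of sqrt(m) * T_c."""
    if not (0.0 <= q1 <= 1.0 and 0.0 <= q2 <= 1.0):
        raise ValueError("q1 and q2 must lie in [0, 1]")
    if q1 + q2 == 0.0:
        raise ValueError("degenerate: q1 + q2 = 0, both species never occur")
    sigma2 = q1 * q2 / (q1 + q2) ** 3
    return AsymptoticVariance(sigma2=sigma2, q1=q1, q2=q2)


def asymptotic_pvalue_from_quad(quad: ContingencyQuad) -> TestResult:
    result = centered_from_quad(quad)
    probs = OccurrenceProbabilities.from_quad(quad)
    var = asymptotic_variance(probs.q1, probs.q2)
    if var.sigma2 <= 0.0:
        raise ValueError(
            "degenerate: asymptotic variance is zero (a constant vector); "
            "the normal approximation does not apply"
        )
    z = (quad.m ** 0.5) * result.centered / var.sigma2 ** 0.5
    result.pvalue = float(2.0 * norm.sf(abs(z)))
    result.method = "asymptotic"
    result.extras = {"z": float(z), "sigma2": var.sigma2}
    return result


def asymptotic_pvalue(y_i: VectorLike, y_j: VectorLike) -> TestResult:
    """Two-sided normal-approximation p-value with plug-in probabilities.

    Computes q1, q2 from the plug-in occurrence probability estimates,
    z = sqrt(m) (T - q1/(q1+q2)) / sigma, and returns 2 (1 - Phi(|z|)).
    """
    return asymptotic_pvalue_from_quad(contingency(y_i, y_j))
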