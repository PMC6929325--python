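# Methods

This note documents the statistical model behind `jaccardtest`, the
numerical choices made where the design was genuinely open, what the
synthetic-data generators do and do not emulate, and the known limitations
of each engine.

## Model and statistic

Two species' occurrence records across *m* units are modelled, under the
null, as independent i.i.d. Bernoulli vectors with occurrence probabilities
p_i and p_j.  The contingency counts (N1, N2, N3, N4) of the patterns
(1,1), (1,0), (0,1), (0,0) are then Multinomial(m; p_i p_j, p_i(1−p_j),
(1−p_i)p_j, (1−p_i)(1−p_j)).  The Jaccard/Tanimoto coefficient
T = N1/(N1+N2+N3) has null expectation E[T] = p_i p_j/(p_i+p_j−p_i p_j) —
exactly, for every m, because N1 given the union size is binomial with that
success probability.  An empty union makes T a 0/0; the refined definition
assigns T its expectation there, so the centered statistic T_c = T − E[T]
of an empty-union pair is exactly zero (no evidence either way).  A pair of
two all-zero vectors additionally has an undefined expectation estimate and
is treated as a degenerate input: the low-level functions raise, and the
screening pipeline avoids it by dropping constant species up front.

All two-sided p-values are of the form P(|statistic| ≥ |observed|) under
the null multinomial law.

## Exact critical region with estimated probabilities

When p_i, p_j are unknown they are estimated by the observed frequencies
p̂.  Plugging p̂ into the expectation for *every* enumerated state would
bias each state's expectation toward the observed coefficient and make the
test conservative; instead the region re-estimates the probabilities from
each configuration separately (p̃_i = (N1+N2)/m, p̃_j = (N1+N3)/m) and
collects states with

    | N1/(N1+N2+N3) − p̃_i p̃_j/(p̃_i+p̃_j−p̃_i p̃_j) | ≥ |T̂_c|,

weighted by the multinomial pmf built from the *observed* p̂ (the
per-configuration p̃ de-biases the region, not the measure).  Numerical
conventions:

* empty-union states get statistic 0, mirroring the refined-coefficient
  convention, so they enter the region only when the observed statistic is 0;
* the comparison is inclusive, with an absolute guard of 1e−12: a state
  whose statistic lands within 1e−12 *below* the threshold is still counted.
  The guard protects discrete ties from floating-point exclusion; its size
  is far below the coarsest statistic spacing (~1/m²) at any feasible m;
* enumeration is lexicographic in (n1, n2, n3), vectorised over the whole
  C(m+3,3)-state table, with the per-state statistic cached per m;
* exact enumeration refuses m above a configurable cap (default 1000),
  directing users to the estimation engines — the state space grows as m³.

## Measure-concentration bounds

The multinomial measure concentrates around its mode, so a set I_ε with
mass ≥ 1−ε can be far smaller than the simplex.  The mode is found by hill
climbing from the componentwise-rounded mean (repaired to sum to m by
adjusting the largest cell); unimodality makes the local maximum global.
The set grows by best-first expansion over the neighbor graph (neighbors
move one element between classes; a pmf-keyed priority queue), which
reaches the target mass with the fewest states — any complete expansion
order yields the same guarantee.  Restricting the critical-region sum to
I_ε gives p_L ≤ p_exact ≤ p_L + ε; the reported p-value is p_L, with both
bounds in the result's extras.  Consequences users should know:

* the region test inside the sum reuses the exact engine's per-state
  statistic and tie guard, so p_L is a strict subset sum of the exact
  computation and the sandwich holds bitwise;
* p_L can be 0 when the true p-value is below ε — read p_upper (= p_L + ε)
  for the guaranteed ceiling;
* default ε = 1e−5; zero-probability cells (a species estimated absent
  everywhere) are simply never entered by the expansion;
* concentration sets depend on the pair only through (m, marginal counts,
  ε) and are cached, which makes matrix screens and simulation studies
  dramatically cheaper than one build per pair.

## Asymptotic approximation

The multinomial CLT plus the delta method for g(x1,x2) = x1/(x1+x2) give
√m·T_c → N(0, σ²) with σ² = q1 q2/(q1+q2)³, where q1 = p_i p_j and
q2 = p_i + p_j − 2 p_i p_j.  Carrying out the quadratic form
∇g Σ ∇gᵀ with Σ = [[q1(1−q1), −q1q2], [−q1q2, q2(1−q2)]] and
∇g = (q2, −q1)/(q1+q2)² collapses to q1 q2 (q1+q2)/(q1+q2)⁴; a variant
formula with an extra (1−q2) factor circulates in the literature but does
not satisfy this identity — it understates the variance and inflates |z| by
1/√(1−q2) permanently (the error does not vanish with m).  Monte-Carlo
simulation at m = 2000 (10⁵ draws) matches the form used here to within
sampling error and excludes the (1−q2) variant by a factor of two.

The two-sided p-value is 2(1−Φ(|z|)), z = √m·T_c/σ̂, with plug-in q̂'s.
Even with the correct variance this is a large-m device: at m = 100 the
discrete, skewed null makes the normal tails inaccurate (the engine fails
strict uniformity checks at every occurrence probability tested, while
being roughly conservative in the FDR study).  The pipeline therefore
defaults to the measure-concentration engine; the asymptotic one is for
situations where runtime is the binding constraint.

## Bootstrap

Each iteration resamples the m positions of each vector independently with
replacement, which destroys any dependence while preserving the marginal
occurrence frequencies, and computes the centered statistic with the
expectation re-estimated *from the resample* — re-estimating per iteration
avoids freezing in the single observed estimate.  The empirical p-value is
(1 + #{|stat_b| ≥ |observed| − 10⁻¹²})/(B+1): the pseudocount keeps
p-values strictly positive (slightly conservative, order 1/B), and the tie
guard matches the exact engine's region convention — without it,
floating-point ties would break the bootstrap's Monte-Carlo convergence to
the exact p-value, whose null law (multinomial at p̂ with per-resample
re-centering) is precisely the distribution being sampled.

The default B = 5m follows the usual resolution recommendation (B at least
5–10 times m).  The resample draw order is fixed (pair-major, vector i
before j), so a seed fully reproduces the statistics.  The empirical null
is centered only up to the Jensen bias of the re-estimated expectation,
which is O(1/m) — an order smaller than the O(1/√m) null spread, and
absorbed into the two-sided comparison.  Pooling null statistics across
pairs of equal length raises the p-value resolution to
1/(n_pairs·B + 1) for large screens.

## Storey q-values

π₀ (the proportion of truly independent pairs) is estimated from the
p-value histogram.  Two estimators are provided: the λ-grid smoother
(grid 0, 0.05, …, 0.90; cubic-polynomial extrapolation at the grid's upper
end; the cited methodology's default) and a single fixed-λ estimate
#{p > λ}/(n(1−λ)) at λ = 0.5.  Both are clipped to (1/n, 1].  Q-values are
the monotone step-up transform q_(i) = min over j ≥ i of π₀·n·p_(j)/j,
capped at 1, and are invariant to the input order.

The screening pipeline and the FDR study harness default to the fixed-λ
estimator.  Reason: all four engines produce p-values with discrete
supports, and the enumeration-based null distribution at moderate m has a
systematic deficit of p-values just below 1 (measured: P(p > 0.9) ≈ 0.056
instead of 0.10 at m = 200), which the λ→1 smoother extrapolates into a
~25% underestimate of π₀ and hence into anti-conservative q-values.  The
fixed λ = 0.5 estimate sits in the flat, well-behaved part of the grid.
The smoother remains available (`pi0_method="smoother"`) and is the better
choice for continuous, well-mixed p-value collections.

## Synthetic data

`simulate_null_pairs` draws mutually independent i.i.d. Bernoulli(p)
vector pairs — the calibration condition (m = 100, 2000 pairs,
p ∈ {0.1, 0.3, 0.5, 0.7, 0.9}).  `simulate_mixture` emulates the FDR study
design: one query vector plus n companions of which ⌈π₀·n⌉ are independent
and the rest dependent.  The dependence mechanism — copy the query's entry
with probability ρ, else draw fresh Bernoulli(p), default ρ = 0.5 — is this
package's own declared choice: it spans independence (ρ=0) to identity
(ρ=1) and preserves the Bernoulli(p) marginal.  FDR conclusions are
therefore qualitative properties of the method (calibration of mean FDP
against the q-threshold), not reproductions of any particular dependent
data-generating process.  Ground-truth labels are returned so observed
false-discovery proportions are computed exactly, with no estimation in
the scoring path.

Study sizes used by the test suite and the acceptance script are
desk-scale choices: the FDR study runs n = 500 companions and 5 replicates
per scenario (m = 200, p = 0.5, π₀ ∈ {0.25, 0.50, 0.75}); full-size
parameters are plain function arguments.  All stochastic studies derive
per-replicate streams from a master seed.

What the generators do *not* emulate: spatial or phylogenetic correlation
between units, heterogeneous per-unit occurrence probabilities, more than
pairwise dependence structure, and missing observations (cells must be
0/1; the method has no missing-data theory).  Passing tests demonstrate
correctness of the computations and calibration under the i.i.d. Bernoulli
null — not robustness to those real-data features.

## Known limitations

* **Discreteness at extreme marginals.**  At m = 100 the exact/MCA/
  bootstrap p-values are uniform in distribution for p = 0.3–0.7 but fail
  a strict two-sided KS uniformity check at p = 0.1 and 0.9: the statistic's
  support is coarse when vectors are sparse or dense, creating mid-range
  p-value atoms (e.g. P(p ≤ 0.5) ≈ 0.61 at p = 0.1) even though the
  small-p tail — the part that drives error control — remains conservative.
  This is a property of the discrete test itself, verified against the
  brute-force oracle, not an implementation artifact.
* **Exact engine cost.**  O(m³) states; the vectorised implementation is
  practical to m of a few hundred and refuses m > 1000 by default.
* **Asymptotic engine.**  Unreliable tails at moderate m; see above.
* **Pipeline scope.**  Binary data only; similarity measures other than
  Jaccard/Tanimoto, abundance weighting, and one-sided tests are out of
  scope.  A variance-scaled version of the centered coefficient is
  sometimes alluded to in the literature without a definition and is not
  implemented.
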