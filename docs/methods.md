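# Methods

## The problem

Given K independent two-arm studies with binomial outcomes, test
H₀: θ₁ = … = θ_K, where θ_i is the log odds ratio of study i. The test
statistic throughout is Cochran's Q, the inverse-variance weighted sum of
squared deviations of per-study effect estimates from their weighted
mean. Everything in this package concerns what distribution to refer Q to
when the studies are of small or moderate size.

## Effect estimation

Log odds are estimated with the ½-corrected empirical logit
L_½(x) = log[(x+½)/(n−x+½)], the unique member of the L_a family whose
O(1/n) bias terms all vanish; its first moment error is O(1/n²). The
variance estimate is the four-term reciprocal sum with ½ added to each
cell, which is finite for every table, so the ½-corrected pipeline needs
no zero-cell special-casing.

The *standard* Q (`q_standard`, used by the chi-square comparator) applies
no correction except to tables containing a zero cell, which get ½ added
to all four of their cells (and only those tables). This matches the
default behaviour of mainstream meta-analysis software; the test suite
asserts agreement with R metafor (`escalc(measure="OR")`, add = ½,
to = "only0", equal-effects QE) to 1e−10 relative on random datasets with
and without zero cells.

## The null moments of Q

Under H₀ the distribution of Q depends on θ, the arm sizes, and a
per-study nuisance parameter ζ_i (control-arm log odds). The estimated
weight is an explicit function of the estimates, ŵ_i = f_i(θ̂_i, ζ̂_i)
with 1/f = (2+2cosh(θ+ζ))/(n_T+1) + (2+2cosh(ζ))/(n_C+1); this identity
with the reciprocal variance estimate is exact and is asserted to 1e−12
in the tests.

`expected_q_theoretical` implements a delta-method expansion of E[Q]:
Q is Taylor-expanded in the 2K estimates about the null point, and
expectations are taken keeping terms of order O(1) and O(1/n). The
ingredients are:

* **Exact arm moments.** Moments of L_½(X) − logit(p), orders 1–4, by
  full summation over the n+1 binomial outcomes with log-space
  probabilities (no Gart-style asymptotic approximations). Exhaustive
  2-D enumeration over all (x, y) pairs validates the derived mixed
  moments of (Θ, Z) = (θ̂−θ, ζ̂−ζ) to 1e−12 for arms up to size 6.
* **Analytic weight derivatives.** Partials of f to total order two via
  the chain rule on g = 1/f; finite differences serve as the test oracle
  only (first partials at 1e−6 relative; second partials via
  Richardson-extrapolated central differences).
* **Cross-study terms.** The i≠j double sums are evaluated in O(K) via
  factorisation into per-study sums; a naive O(K²) double-loop assembly
  is kept in the test suite as an algebra oracle. The full assembly is
  additionally tested against finite-difference Taylor coefficients of
  the explicit Q function for unequal K=3 studies (agreement limited only
  by FD truncation, asserted at 5e−4 relative).

Cross-study terms use the exact per-study moments throughout (the choice
between exact and order-1/n-truncated moments inside those sums is
immaterial at the expansion's own order; we use exact everywhere for
definiteness).

For the plug-in test the expansion is evaluated at θ = θ̂_w and
ζ_i = ζ̂_i = L_½(y_i), with theoretical weights w_i = f_i(θ̂_w, ζ̂_i) —
not the data weights.

## Calibration and the gamma reference

The expansion reliably identifies *where* corrections to the chi-square
moments are needed but over-predicts their size; the linear relation

    (K−1) − E[Q] = 0.687 · [(K−1) − E_th[Q]]

maps it onto simulated means, and the variance is taken from the fitted
quadratic Var[Q] = 4.74(K−1) − 12.17·E[Q] + 9.42·E[Q]²/(K−1) (positive
for any real mean — the per-(K−1) quadratic has negative discriminant;
at E[Q] = K−1 it returns 1.99(K−1), essentially the chi-square value).
The constants 0.687 / 4.74 / −12.17 / 9.42 are adopted as published and
are not refitted here.

These are *global* regressions with reported fit quality R² ≈ 97.0% and
98.5%. Our own cross-check against direct simulation of Q (50,000–100,000
replicates, six scenarios spanning K ∈ {5,10,20}, N ∈ {90,150,210},
q ∈ {⅓,½,⅔}, p_C ∈ {0.1,0.2,0.4}, θ ∈ [0,2]) finds per-scenario residuals
of up to ~2% in the mean and ~7% in the variance. That is the intrinsic
accuracy of the calibration: the residuals are regression error, not
Monte-Carlo noise, and do not shrink with more replicates. The unit
suite therefore asserts those relative bands; comparisons at a few
Monte-Carlo standard errors of a large simulation are expected to fail
for some scenarios, and do.

The gamma reference is matched by α = E[Q]²/Var[Q], β = Var[Q]/E[Q], and
the p-value is the gamma upper tail at Q. In a harsh scenario (K=10,
N=90, p_C=0.1, θ=0) the Kolmogorov–Smirnov distance of 10⁴ simulated Q
values to this gamma is more than 3× smaller than to χ²(K−1).

If the corrected mean is nonpositive (theoretically possible for extreme
inputs far outside the calibrated grid) the gamma test raises
`DegenerateNullError` rather than fabricating a reference distribution.

## Breslow–Day and Tarone

The Breslow–Day statistic compares observed treatment-arm events x_j to
their expectations A_j under the Mantel–Haenszel common odds ratio ψ̂,
scaled by asymptotic variances
Var_j = [1/A_j + 1/(n_Tj−A_j) + 1/(m_j−A_j) + 1/(n_Cj−m_j+A_j)]⁻¹, and is
referred to χ²(K−1). A_j solves a quadratic with the admissible root
selected inside (max(0, m_j−n_Cj), min(m_j, n_Tj)); within 1e−12 of ψ = 1
the linear (hypergeometric-mean) branch is used for stability. The Tarone
adjustment subtracts (Σ(x_j−A_j))²/ΣVar_j; on well-behaved data the two
are virtually identical. No ½-corrections are applied inside this test —
the formula uses raw counts.

Studies with degenerate margins (no events or all events) carry no
information about the odds ratio: they are dropped from the sum, degrees
of freedom are reduced accordingly, and a warning is attached. If fewer
than two informative studies remain, or the Mantel–Haenszel ratio is
inestimable, the test is reported undefined — for very sparse data this
happens with appreciable probability, which is exactly the situation in
which the gamma-referenced Q (always defined) is the recommended fallback.
Implementation agreement with statsmodels'
`StratifiedTable.test_equal_odds` (both adjusted and unadjusted) is
asserted to 1e−10 in the tests.

## Simulation engine

`simulate_level` draws x_i ~ Bin(n_Ti, p_Ti), y_i ~ Bin(n_Ci, p_Ci) with
p_Ti = expit(logit(p_Ci) + θ); `simulate_power` first draws per-study
θ_i ~ N(θ, τ²). With τ = 0 the normal draw is skipped entirely so power
simulations reduce bit-for-bit to level simulations at the same seed.
One seeded generator serves each call, and all tables for a scenario are
drawn before any test runs, so adding or removing tests never perturbs
the data stream. Treatment probabilities pushed to the boundary by
extreme random-effects draws are clamped to [1e−12, 1−1e−12] and the
clamp count is reported (relevant only for θ = 3 with large τ).

Rejection is p < nominal; replicates on which a test is undefined are
excluded from that test's denominator and counted. The Monte-Carlo
standard error is √(p̂(1−p̂)/n_valid).

The scenario grids mirror the study conditions the calibration was built
for: the homogeneous grid crosses K ∈ {5,10,20,40}, N ∈ {90,150,210},
q ∈ {⅓,½,⅔}, p_C ∈ {0.1,0.2,0.4}, θ ∈ {0,0.5,1,1.5,2,3} (648 scenarios);
the heterogeneous designs use the skewed size vectors averaging
90/150/210 with per-θ probability vectors, in aligned and reversed
pairing orders, repeated ×2/×4/×8 for K = 10/20/40. Default replicate
counts are 10,000 (K ≤ 20) and 1,000 (K = 40). Arm sizes use
n_C = round(q·N), exact integers everywhere on the grid.

The default test-suite runs use reduced replicate counts (a few thousand
per scenario, with tolerance bands of ±0.015 on achieved levels) so the
whole suite stays desk-scale; the full grids are exposed as library
functions for larger studies.

### What the generator does and does not emulate

The generator reproduces the two-arm binomial sampling model with fixed
or normally-distributed study effects — the model under which the
calibration constants were fitted and under which the level/power claims
hold. It does not emulate features of real meta-analyses such as
selective publication, correlated arms, non-binomial overdispersion
within arms, or informative study sizes; passing tests therefore support
the distributional claims about Q under the stated model, not robustness
to those violations.

## Known limitations

* The achieved level of the chi-square comparator in the rare-event
  scenario (N=90, q=½, p_C=0.1, θ=0) is ~0.014 at K=5 in our
  reimplementation, dropping below 0.01 only from K=10 upward — the
  qualitative collapse is as published, but the sub-0.01 bound does not
  hold at K=5 here.
* The calibrated moments inherit the published regression constants'
  per-scenario residuals (see above); the gamma reference is an
  approximation, not an exact finite-sample distribution.
* Only log odds ratio effects with the ½ (or 0) continuity correction
  are supported; relative risks, risk differences and other corrections
  are out of scope, as are τ² estimation and I².
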