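# Methods

## Problem and statistic

`saddleperm` performs k-sample comparisons in cluster randomized
trials whose endpoint is a derived, right-censored quantity: a ratio
`T = X1/X2` of two positive measurements, or a product `T = prod X_l`
analysed on the log scale.  Both are treated as generalized event
times, so the inference is rank-based and distribution-free.

Each subject i receives a censoring-adjusted weighted log-rank score
over the pooled sample of all M subjects,

    w_i = W(T_i) d_i - sum_{t_j <= T_i} W(t_j) d_j / n_j,

with `W = 1` (log-rank), `W = n_j` (Gehan–Wilcoxon) or `W = S(t-)`
(Prentice–Wilcoxon, left-continuous pooled Kaplan–Meier).  Tied event
times share one risk-set row; censored observations tied with an event
remain at risk at that time.  Scores are summed within each of the N
randomization clusters into C_1..C_N (they sum to zero), and the
group totals W_j (j = 1..k-1) form the test vector.  Under the urn
design — all allocations with the target arm sizes N_1..N_k equally
likely — the exact covariance of W is the finite-population matrix

    Var(W_j)     =  N_j (N - N_j) / (N - 1) * S_C^2,
    Cov(W_j,W_l) = -N_j N_l / (N - 1)       * S_C^2,

with `S_C^2 = (1/N) sum C_c^2` (divisor N, as the exact permutation
variance requires), and the global statistic is the quadratic form
`Q = W' Sigma^{-1} W`.

## Two chi-squared calibrations

`(N-k) SSB / SSW` (between over pooled-within sum of squares of the
cluster scores) is a strictly increasing function of Q
(`Q = (N-1) SSB / (SSB + SSW)`), so every permutation engine is
identical for the two forms.  Their large-sample chi-squared
calibrations are not:

* the **conventional analysis** refers `(N-k) SSB / SSW` to
  chi-squared with k-1 df, ignoring the sampling noise of the
  estimated within variance.  With few clusters per arm this is
  anti-conservative (essentially using chi-squared where an F with few
  denominator df would be honest, aggravated by heavy-tailed cluster
  scores under strong intra-cluster correlation).  This is the
  comparator whose Type I error inflates in the simulation study and
  is the headline `p_chisq` of `run_test`;
* referring Q itself (exact permutation covariance) to chi-squared is
  mildly *conservative* at small N, because the permutation law of Q
  has bounded support.  It is reported in the diagnostics
  (`p_chisq_exact_sigma`) and available as the experiment engine
  `chisq_exact_sigma`.

## Analytic permutation tail

The permutation null of Q is approximated without enumeration:

1. **Surrogate and conditioning.**  Labels are modelled as independent
   multinomial draws with `p_j = N_j/N`.  Conditioning on the realized
   group counts restores sampling without replacement exactly, so the
   count-conditioned law *is* the urn law.  The joint cumulant
   generating function of (W, counts) is a sum of per-cluster
   log-sum-exp terms with closed-form gradient and Hessian.
2. **Double-saddlepoint density.**  For a target w the joint tilt
   solves `grad K(s, phi) = (w, n)` by damped Newton (tolerance
   `1e-10 (1 + |target|)`, step halving, at most 50 iterations);
   the conditional density is
   `det K''(s^, phi^)^{-1/2} exp(K - s'w - phi'n)` up to a constant.
   The count-conditioned curvature at zero tilt is `((N-1)/N) Sigma`;
   this is a property of the Laplace geometry, not a mis-scaling —
   forcing it onto Sigma by rescaling the scores changes the targeted
   law and measurably inflates tails.
3. **Spherical–radial reduction.**  In Sigma-standardized coordinates
   `{Q >= q}` is the outside of a sphere of radius sqrt(q).  The tail
   is the ratio of radial integrals of `rho^{d-1} J(rho)`, where
   `J(rho)` averages the density over a fixed antithetic direction set
   (d = 1: two points; d = 2: equally spaced angles; d >= 3: columns
   of Haar-random orthogonal frames from a fixed internal seed;
   12–32 antithetic pairs depending on d).  Antithetic pairs cancel
   the odd (skewness) part of the exponent exactly, so the angular
   average converges quickly.  Radial integrals use Gauss–Legendre
   panels split at sqrt(q); normalizing by the full integral removes
   the constant-order error of the raw saddlepoint density.  With a
   Gaussian CGF the density is exact and the pipeline reproduces the
   chi-squared tail to quadrature accuracy (~1e-6 relative), which is
   the built-in check of the scalar reduction.
4. **Hull guard.**  The attainable W set is a bounded polytope; as a
   tilt approaches its boundary the Laplace prefactor diverges.  Along
   each ray the profile is clamped to be non-increasing after its
   first descent (the true radial profile is unimodal), targets with
   no saddle contribute zero mass, and the mode value at w = 0 anchors
   the floor that prunes negligible points.  Newton runs are
   warm-started along each ray (numba kernels; typically 2–6
   iterations per node).

A Lugannani–Rice cross-check is reported in the diagnostics: the
constrained maximum of the exponent on the shell gives the signed root
r, the Lagrange multiplier gives the scalar saddle t^ (by implicit
differentiation of the profile), and `1 - Phi(r) + phi(r)(1/u - 1/r)`
is evaluated alongside.  Note the correction term's sign: with
`r = sign(t) sqrt(2(t q - K(t)))` and `u = t sqrt(K''(t))` the formula
must carry `1/u - 1/r`; the reversed sign moves it away from exact
benchmark tails (e.g. the unit exponential).  The reported tail is the
quadrature value, which is what the chi-squared-limit accuracy
requirement demands; an LR step applied to a chi-square-shaped scalar
CGF is roughly 1–2% off at moderate Q and could not meet it.

An optional second-order density factor
`1 + k4/8 - (2 k13 + 3 k23)/24` (tilted-cumulant contractions through
the inverse Hessian, evaluated at radial anchors and interpolated) is
implemented (`SaddleConfig.use_correction`); it is off by default
because at study-scale designs it overshoots downward about as much as
the uncorrected profile overshoots upward, while costing ~5x.

Since the analytic law is continuous, the analytic mid-p equals the
tail; atoms are computed only by the enumeration engine
(`P(Q > q) + P(Q = q)/2` with a 1e-9 tie tolerance) and estimated by
the Monte Carlo engine.

### Accuracy envelope

Against exact enumeration (the definitive oracle) the analytic tail at
enumerated support points tracks the exact mid-p with median relative
error of a few percent for designs with >= 5 clusters per arm
(e.g. ~2–4% at N = 12–16, k = 2–3), and against 300k-permutation Monte
Carlo at study scale (N = 25–30, k = 5–6) the error near p = 0.05 is
typically +2–7% relative, which keeps the rejection-rate gap to the
mid-p engine within 0.005.  For micro designs (arms of 2–3 clusters,
N <= 10) the support hull sits at ~2 standardized units and the
Laplace density degrades near it; relative errors there can exceed
10% and reach ~100% at extreme atoms.  The corresponding acceptance
check is left failing rather than loosened: at those sizes the exact
and Monte Carlo engines are the appropriate tools (and the package
auto-selects enumeration when the permutation space is small).

## Confidence intervals

Pairwise test inversion: for a target arm versus a reference, a grid
of multiplicative candidates theta (additive Delta on the log-product
scale) is scanned; each candidate divides the target arm's observed
times by theta (censoring indicators untouched — the transform models
the whole observation-time distribution), the statistic is recomputed,
and the interval is the connected accepted set (p > alpha) around the
maximal-p candidate, with optional bisection refinement of the
endpoints and a warning listing disconnected accepted candidates.
Non-target arms are held at their null value.  The Monte Carlo engine
reuses one seed across a profile, making it a deterministic function
of (data, grid, seed).  Under null data, inversion duality makes
"interval covers the truth" literally the event "test at the truth not
rejected"; the coverage experiments exploit this identity and
spot-verify it replicate-by-replicate with explicit inversions.

## Synthetic-data generator

The generator emulates cluster randomized trials under the global
null.  Per dataset: cluster sizes (balanced m, or per-cluster discrete
uniform [a, b]); gamma frailties with mean 1 and variance theta
(`Gamma(1/theta, theta)`; all ones at theta = 0); positive components
per subject; the derived endpoint; independent exponential censoring;
urn allocation with equal arm sizes (remainders to the lowest-indexed
arms).  The 20-scenario registry fixes (k, N, size rule, theta,
censoring target, weight scheme) spanning k = 5–6, N = 25–180,
theta = 0–0.75 and ~20%/~40% censoring.

Choices where the protocol is open, with rationale:

* **Frailty placement.**  For ratios the frailty multiplies the hazard
  of the numerator component only: scaling both components identically
  cancels in X1/X2 and produces no intra-cluster correlation (a unit
  test demonstrates the cancellation).  For products it scales every
  component.  Both placements are switchable in `GenConfig`.
* **Hazard-scale coupling.**  With hazard-multiplicative frailty the
  Weibull-component ratio is a deterministic monotone transform of the
  exponential-component ratio given the same draws, so the two
  component families give *identical* rank-statistic distributions —
  consistent with the near-identical Weibull/exponential columns of
  the reference study.
* **Baseline constants.**  Weibull shape 1.5, scale 1, exponential
  rate 1, p = 2 product terms.  Rank invariance makes operating
  characteristics independent of these marginals; they are recorded
  with every run regardless.
* **Censoring calibration.**  The endpoint's marginal law does not
  depend on cluster sizes, so one pool of 200,000 subjects (fixed
  internal seed) is simulated per distributional configuration and the
  exponential rate solving `E[1 - exp(-rate T)] = target` is bisected
  and cached; achieved fractions are within 0.01 of target.
* **Seeding.**  One root `SeedSequence` per experiment spawns
  per-replicate children, so runs are reproducible and replicates are
  independent.

What passing simulations do and do not show: the generator produces
exchangeable-cluster, shared-frailty dependence with independent
censoring; real trials can add covariate effects, informative cluster
size, non-exponential censoring and ties, none of which are emulated.
Rank-ICC induced by the numerator-only mechanism at theta = 0.75 is
moderate (~0.2–0.3 on the log scale); published high-theta inflation
figures for the conventional test are somewhat larger than this
generator reproduces, so the study replication is faithful in pattern
and approximate in magnitude at high theta.

## Study replication at reduced size

The operating-characteristic tests run 2000 replicates per quoted
scenario (the reference study used 10,000), with B = 2000 permutations
for the mid-p engine, and the explicit-inversion spot check uses 100
replicates on a 15-point grid; these sizes give binomial standard
errors of ~0.005 on a 5% rate while keeping a full run in minutes.
`scripts/acceptance.py` uses 1500 replicates per scenario.

## Known limitations

* Micro designs (N <= 10, arms of 2–3) exceed the analytic engine's
  accuracy envelope (see above); use the exact engine there.
* `conditional_density` is the raw double-saddlepoint density: at
  hull-vertex targets the prefactor diverges, so lattice sums over the
  *entire* attainable set are not near 1 — only bulk-region mass is
  meaningful (the tail engine's envelope exists precisely for this).
* No ties machinery beyond the pooled risk-set convention; no
  left truncation, interval censoring, competing risks, stratified or
  covariate-adaptive designs; no power analysis under alternatives.
* Joint (all-arms) inversion regions are available in principle by
  scanning a joint grid but only pairwise inversion is surfaced.
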