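# Methods

`gvarcomp` estimates the three variance components of the fully crossed
p×i measurement design and, more importantly, the *variability* of those
estimates — their sampling standard errors and 80% intervals — by four
routes (normal-theory ANOVA, delete-one jackknife, six bootstrap
resampling strategies, Gibbs sampling), and provides a Monte-Carlo
harness that compares the routes across four score distributions using
relative percentage bias (RPB).

## Model

Scores follow the additive random-effects decomposition

    X_pi = μ + π_p + β_i + ε_pi ,        p = 1..n_p persons, i = 1..n_i items,

with uncorrelated effects of variances `vc.p`, `vc.i`, `vc.pi` (the
interaction is confounded with residual error because the design has one
observation per cell).  The balanced ANOVA mean squares (MS_p, MS_i,
MS_pi) with degrees of freedom (n_p−1, n_i−1, (n_p−1)(n_i−1)) yield the
moment estimates

    vc.pi = MS_pi,    vc.p = (MS_p − MS_pi)/n_i,    vc.i = (MS_i − MS_pi)/n_p .

Negative estimates are **retained** by default: truncation at zero would
bias replication means upward, and the harness evaluates means across
replications.  `estimate_vc(..., truncate=True)` clips when a
non-negative point estimate is wanted.

## Variability estimators

**Traditional (normal-theory).**  The SE estimator uses the `df+2`
denominators, `SE²(α) = Σ_β 2·[f(β|α)·MS_β]² / (df_β + 2)`, whose square
is unbiased for the sampling variance under normal score effects; the
interval is `vc ± z·SE` with the exact z (1.281552 at the 80% level), not
truncated at zero.  The *population* sampling SD — the "Parameter"
reference — is the same form with expected mean squares and plain `df`
denominators; at 100×20 with components (4, 16, 64) it evaluates to
(1.0287, 5.3988, 2.0869).

**Jackknife (synthesized, facet-matched).**  Pseudovalues
`θ* = s·θ̂ − (s−1)·θ̂₋ⱼ` are formed per facet: persons are deleted for
`vc.p` and `vc.pi` (s = n_p), items for `vc.i` (s = n_i).  The SE is the
standard error of the pseudovalue mean and the interval uses Student t
with s−1 df.  Two alternatives were implemented and rejected on
measurement: (i) a row×column tensor pseudovalue scheme normalised by
s = n_p·n_i treats cells as exchangeable and under-estimates `SE(vc.i)`
several-fold at 100×20, because with n_i ≪ n_p the item facet dominates
that SE; (ii) single-cell deletion through the Henderson missing-cell
estimator (kept as `jackknife.delete_one_cell`, built on
`anova_core.estimate_vc_missing_cell`) is sound on normal scores but
substantially over-estimates `SE(vc.pi)` on heavy-tailed scores, where
the pseudovalue spread is driven by fourth moments of single extreme
cells.
All delete-one re-estimates come from rank-one updates of row/column
sums, so a full jackknife costs O(n_p·n_i).

**Bootstrap.**  Six strategies named by what they resample with
replacement: `boot-p` (whole person rows), `boot-i` (whole item columns),
`boot-pi` (rows and columns independently), and the residual strategies
`boot-pr`, `boot-ir`, `boot-pir`, which operate on the exact additive
decomposition `x = m + a_p + b_i + e_pi`, resample the flagged effect
vectors (residuals pooled over all cells), and hold the un-flagged
effects at their estimates.  Per resample the plug-in ANOVA estimates are
bias-corrected: the resampling expectations `E*[MS*]` are linear in
(MS_p, MS_i, MS_pi) with coefficients built from (n_p−1)/n_p and
(n_i−1)/n_i — derived exactly for each strategy — and the correction
inverts this map, so corrected draws are resampling-unbiased for the
original sample's components (for `boot-p` this reduces to the familiar
n_p/(n_p−1) scaling and the `vc.i − vc.pi/(n_p−1)` adjustment).  SE is
the B−1 standard deviation of the corrected draws (B = 1000 by default);
the 80% interval takes their 10th/90th percentiles with linear
interpolation.  Index streams are drawn in the fixed order persons,
items, residuals from the per-call seed.

**MCMC.**  A Gibbs sampler for the same model with conjugate priors:
flat on μ, normal on the effects, and inverse-gamma hyperpriors τ(a, b)
on the variances, read as shape a and *scale* b so that with the default
shape 2 the prior mean is b.  The default scales (4, 16, 64) center the
priors on the normal-family generating components; in the study harness
the scales are re-centered on each family's population components
(`PriorSpec.centered_on`), mirroring that practice.  All variances start
at 0.001, effects at 0.  Default chain: 11 000 iterations, 1 000 burn-in,
no thinning, one chain; convergence is monitored by the split-chain
scale-reduction factor with threshold 1.1 (flagged, not fatal).  Every
variance full conditional is inverse-gamma, so draws are strictly
positive.  Summaries are the posterior mean, posterior SD and the central
80% credible interval of pooled post-burn-in draws.

## Synthetic data

Four generating families at the study design 100×20, all reproducible
bit-for-bit from a seed:

* **normal** — `X = μ + σ_p z_p + σ_i z_i + σ_pi z_pi` with
  (σ_p, σ_i, σ_pi) = (2, 4, 8), i.e. components (4, 16, 64).
* **dichotomous** — `Y = 1{X ≥ 0}` applied to the normal score; each cell
  is Bernoulli(1/2).  The population components follow exactly from the
  bivariate-normal orthant probability: two cells sharing only a person
  (item) have indicator covariance `arcsin(ρ)/2π` with
  ρ = σ²_p/σ²_tot (σ²_i/σ²_tot), giving (0.00758, 0.03050, 0.21192).
  Thresholding is strongly information-destroying: the binary scores
  retain far weaker row/column covariance than the latent normal, which
  is why reference values quoted for this family elsewhere can be
  inconsistent with the construction; this package derives its truth
  analytically from the generator it actually runs (the Monte-Carlo
  moment tests confirm the orthant values).
* **polytomous** — `X = 2·Bern(0.14715) [per person] + 2·Bern(0.0595)
  [per item] + Binom(5, 0.5917) [per cell]`, integer scores 0–9 with
  components (0.5020, 0.2238, 1.2080); this term-to-facet assignment is
  validated by the ANOVA calibration test.
* **skewed** — additive generalized-hyperbolic effects, one draw per
  person, item and cell.  GH(λ=1, α=3, β, δ=1, μ=0) is sampled as a
  normal variance–mean mixture `X = μ + βW + √W·Z` with W generalized
  inverse Gaussian (drawn by `scipy.stats.geninvgauss`); β ∈ {0, −1, −2}
  controls skewness.  The per-effect variance has the Bessel-function
  closed form `E[W] + β²·Var(W)` → 0.5106, 0.6489, 1.6605, verified
  against numerical integration of the GH density.

The generators emulate idealized test data: balanced, complete,
homoscedastic within family, with exchangeable persons and items.  They
do not emulate missingness, item drift, rater effects, or
person–item interactions with structure, so passing tests demonstrate
estimator behaviour under the stated sampling models, not robustness to
those real-data features.

Reference ("Parameter") sampling SDs are analytic for the normal family;
for the other families no distribution-free closed form exists and they
are recomputed by a Monte-Carlo oracle — the SD of the ANOVA estimates
over 2 000 fresh replications with a fixed documented seed
(`anova_core.population_se`, seed 20 000 101).

## Evaluation and the divide-and-conquer rule

`RPB = 100·(estimate − parameter)/parameter`; a quantity is *accurate*
iff |RPB| < 25 (the boundary counts as inaccurate; a zero parameter is
flagged, not divided by).  Interval quality is the RPB of empirical
coverage against the nominal 0.80.  For the bootstrap strategy table,
the admissible set per (quantity, component, distribution) contains the
strategies with |RPB| < 25; a strategy is *optimal* for a column when it
is admissible in **all** distributions, ties broken by the smallest
summed |RPB| across distributions.  In the qualitative grid the
bootstrap row of a distribution counts a component as accurate when at
least one strategy estimates it accurately (the divide-and-conquer
reading); the other methods need all components accurate.

## Study harness and problem sizes

`run_study` seeds every replication as
`SeedSequence([master, dist_index, rep, purpose])`, making results
independent of evaluation order and bit-for-bit reproducible; completed
cells are persisted as CSV and reloaded on resume.  The full study is
R = 1000 replications with B = 1000 bootstrap resamples.  The package's
default comparison profile runs MCMC on the first 200 replications
(`mcmc_replications`), the one expensive estimator; the test suite's
scaled profile uses R = 200, B = 500, MCMC on 100 replications with a
2 200-iteration chain, sizes at which every qualitative conclusion of
the full run is stable while a complete 4-distribution × 4-method grid
re-derives in a few minutes on one core.

## Numerical choices and degenerate inputs

* Percentiles (bootstrap and credible intervals) use NumPy's linear
  interpolation of order statistics.
* Matrices must be finite, complete and at least 2×2 (3×3 for the
  jackknife); unknown strategies, invalid probabilities and
  non-normalizable GH parameters (α ≤ |β|) are rejected.
* A constant matrix yields all-zero mean squares, zero SEs and degenerate
  intervals in every estimator.
* Bootstrap bias correction can produce slightly negative corrected
  draws (as can the plug-in estimates); they are retained for the same
  unbiasedness reason as in the ANOVA route.
* The Henderson missing-cell solver rejects more than one missing cell;
  with none it reduces exactly to the balanced ANOVA solution.

## Known limitations

* Only the fully crossed single-observation p×i design is covered — no
  nested designs, no replicated cells, no missing data beyond the
  single-cell diagnostic estimator.
* The jackknife interval relies on a t approximation of pseudovalue
  means; for the item component with few items (s = n_i) it can
  over-cover slightly.
* The dichotomous family's reference values are derived from its
  construction (orthant formula); see the note above on external
  inconsistencies.
* The Gibbs sampler assumes normal effects for every family; on
  polytomous and highly skewed scores its posterior SDs under-estimate
  the true sampling variability of `vc.i` / all components respectively
  — this is a finding the harness reproduces, not a defect it hides.
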