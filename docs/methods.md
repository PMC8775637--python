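# Methods

## Model

The outcome is a single binary event per observed cyclist: occupying the
motorized vehicle lane (1) or riding normally (0).  All covariates are
categorical and enter as treatment-coded dummies with a leading intercept,
so an L-level variable contributes L−1 columns against an explicit
reference level.  The random-parameter logit lets a chosen subset of
coefficients vary across observations with independent normal mixing
distributions:

- y_i ~ Bernoulli(p_i), logit(p_i) = β_i · x_i
- β_{i,k} ~ N(μ_k, Σ_k) for k in the random set; β_{i,k} = μ_k otherwise
- μ_k ~ N(a, b), Σ_k ~ InverseGamma(c, d)

Defaults a = 0, b = 10⁶, c = d = 0.001 — vague priors in which the data
dominate wherever they carry information.  The mixing covariance is
diagonal by design; correlated random coefficients, non-normal mixing
distributions and frequentist simulated-ML mixed logits are out of scope.

Which coefficients are random is **configuration, not inference**: the
packaged template for the pooled model marks the six contrasts reported
with a parameter-distribution SD in the motivating study (middle-aged,
barriers strip, two motor lanes, medium bike volume, medium vehicle
volume, evening peak), and the per-facility templates mirror the
corresponding published tables.

### Observation-level vs group-level random parameters

The literal model indexes β by observation: each rider has one Bernoulli
trial and their own coefficient draw.  In that regime Σ_k is informed only
through the marginal likelihood (differential attenuation across covariate
cells) and is weakly identified; the package therefore also exposes a
group-level mode (`run_chain(..., groups=...)`) in which riders in the
same group — a site, or site-period — share one realisation of each random
coefficient.  With repeated trials per effect the mixing SD becomes well
identified.  Which regime generated real field data is not knowable from a
published table; both are first-class here.

## Sampler

Metropolis-within-Gibbs, two chains by default:

1. **Random-coefficient sweep.**  Given (μ, Σ), the full conditionals of
   the β_i factorise over observations (each observation's likelihood
   involves only its own coefficients), so a vectorised random-walk
   Metropolis step proposes and accepts all n (or all G groups') values of
   one random column simultaneously.
2. **Conjugate hierarchy.**  μ_k | β, Σ_k is normal with variance
   1/(n/Σ_k + 1/b) and mean pulled between the coefficient average and the
   prior; Σ_k | β, μ_k is InverseGamma(c + n/2, d + ½Σ(β_{i,k} − μ_k)²).
3. **Fixed-coefficient block.**  The fixed μ's update by a single block
   random-walk Metropolis whose proposal covariance is the
   Laplace-approximation covariance (inverse observed information at the
   maximum-likelihood fit plus the prior precision), scaled by 2.38/√dim.
   The prior-precision term keeps the proposal bounded under
   (quasi-)separation, where the raw information matrix is near-singular.
4. **Group moves.**  Two additional Metropolis moves per random column
   repair the slow mixing of the centred parameterisation: a joint
   translation of (μ_k, β_{·,k}) by a common δ, and a joint rescaling
   Σ_k → tΣ_k, β_{·,k} → μ_k + √t(β_{·,k} − μ_k) proposed on the log scale
   (acceptance includes the map's Jacobian, which reduces to +log t).
   Both leave the posterior invariant; without them the degenerate-variance
   regime (Σ pinned near 0) mixes at rate O(Σ/n) and effectively freezes.

Proposal scales adapt only during burn-in, nudged whenever a windowed
acceptance rate leaves [0.2, 0.5] (the β-sweep equilibrates near 0.3–0.45);
the post-burn-in kernel is fixed, so the stationary distribution is exact.
Correctness is contracted by quadrature tests: on a 3-observation fixed
model and on a 2-observation random-intercept model (4-dimensional grid),
pooled MCMC marginals match grid posteriors to total variation < 0.05.

Chain 1 starts at zeros; chain 2 at the ML fixed-logit estimates (clipped
to ±10 against separation blow-ups) jittered by N(0, 0.5²).  Mixing
variances start at 0.1.  Σ draws below 10⁻⁸ are rejected states, keeping
density evaluations finite.  Convergence is monitored by the classic
Gelman–Rubin potential scale reduction factor per μ_k and Σ_k; exactly
constant chains (degenerate but converged) report 1.0.  If any posterior
coefficient mean exceeds 10 in absolute value the fit warns about probable
separation — under the vague prior the posterior genuinely drifts in that
case, and the warning is the documented behavior rather than an error.

## Summaries

Draws are pooled across chains.  Tables report posterior mean, SD,
equal-tailed 2.5%/97.5% quantiles, and OR = exp(posterior mean).  For
random coefficients, σ̂_k is the posterior mean of √Σ_k and the
heterogeneity shares are the plug-in values Φ(μ̂_k/σ̂_k) and its
complement — the same arithmetic as the published tables, which the
analytic regression tests verify row by row.  A draw-wise alternative
(posterior mean of Φ(μ/σ) across draws) is available behind
`summarize(..., share_from_draws=True)`.

DIC is the conditional version: D̄ is the mean of the per-draw deviances
−2·log f(y | β); D̂ plugs in the posterior means of the parameters that
actually enter the likelihood (β_{i,k} for random coefficients, μ_k for
fixed ones); p_D = D̄ − D̂.  `compare_models` applies the strict rule that
only a difference **greater than** 10 excludes the higher-DIC model, and
refuses to compare results fitted to different data (fingerprint check).

A known property of this DIC, confirmed here empirically, is that it
cannot reliably detect *observation-level* heterogeneity with one
Bernoulli trial per effect: the plug-in deviance gain from fitting each
rider's β_i approximately cancels against p_D, so the comparison is a wash
regardless of the true mixing SD.  With group-level heterogeneity
(repeated trials per effect) the comparison behaves as intended — the
model-selection validation study uses a random intercept across 50
site-like groups with σ = 0.5 at n = 5,000, where the random-parameter
model wins decisively and the exclusion rule fires.  The
observation-level wins count is reported alongside as an informational
metric.

## Collinearity screen

Pearson correlations over all non-intercept dummy columns (point-biserial
against the binary outcome is the same Pearson formula).  Pairs with
|r| above the threshold — default 0.7, the conventional severe-collinearity
rule of thumb; the choice is a configuration knob — are resolved
deterministically: the member with the larger |corr(column, outcome)| is
retained, ties breaking in design order, every decision logged.  The
procedure iterates until no retained pair exceeds the threshold, which
makes it idempotent and row-order invariant.  A variable leaves the model
only when all of its dummies are dropped.  The deterministic rule is this
package's substitute for the informal refit-and-inspect procedure
described in the motivating study; it is documented as such, not claimed
as the original authors' algorithm.

## Synthetic data

The generator emulates the field study's structure: fourteen categorical
variables with the observed marginal frequencies (exact counts/34,631, of
which the published percentages are roundings), one pseudo-random stream
per variable split deterministically from the dataset seed (adding a
variable never perturbs the others), and outcomes drawn from a
user-specified random-parameter logit with realized coefficients stored
losslessly.  Two sampling modes:

- **independent** (default): variables sampled independently — the study
  reports only marginals, and independence gives clean recovery tests;
- **site-block**: road-geometry variables (dividing strip, lane width,
  motor-lane count, on-street parking) inherited from one of the eight
  surveyed site profiles, weighted to preserve the dividing-strip
  marginals — reproducing the perfect nesting of geometry within sites
  that real data exhibit, hence realistic confounding.

What the generator does *not* emulate: within-day temporal autocorrelation,
continuous trajectories, weather–volume dependence, or any cross-variable
association beyond the site-block nesting.  Passing recovery tests
therefore demonstrate correctness of the estimator under the assumed
sampling process, not robustness to the full dependence structure of field
observations.

Volume classes are sampled as categories directly (the analysis models
them as classes; raw counts are never needed).

## Validation studies (the acceptance suite)

Study conditions, chosen once:

- **Grid oracle**: n = 3 fixed model, N(0, 4) priors (informative so the
  grid captures the mass), 241-point grids, 2 × 35k kept draws.
- **Recovery**: 20 replicates, n = 5,000, full 14-variable design with the
  published pooled coefficient means as fixed truth, gender contrast
  random at (0.6, 0.3); 2 chains × 4,000 iterations (2,000 burn-in).
  Asserted: μ interval coverage ≥ 90%, σ coverage ≥ 80%.  The published
  means make the design informative enough that σ is genuinely (if
  weakly) identified at the observation level; with a sparser design the
  σ posterior has a flat ridge and coverage degrades — that behavior is
  the identifiability caveat above, not a sampler defect.
- **Model selection**: 20 replicates, group-level random intercept,
  σ = 0.5, 50 groups, n = 5,000.  Asserted: random-parameter DIC wins and
  the >10 exclusion rule fires in ≥ 16/20.
- **Degeneracy**: InverseGamma(10⁴, 10⁻²) pins Σ near 10⁻⁶; the
  random-parameter μ posterior means must match the fixed-logit means
  within 0.05 on shared n = 2,000 data.
- **ML agreement**: n = 10,000 fixed-effects data; posterior means must sit
  within 2 standard errors of the statsmodels ML estimates.  The ML
  standard error is the comparison scale because the posterior mean and
  the MLE differ by a genuine O(1/n) offset that no chain length removes.

Iteration counts are the sizes at which the diagnostics (PSRF < 1.1,
stable pilot results) were satisfied; they keep a full validation pass in
the minutes range on a single CPU.

## Published-table regressions and known inconsistencies

All 94 printed OR rows satisfy |exp(mean) − OR| ≤ max(0.001,
0.0005·(1 + OR)) — the exact propagation of three-decimal rounding through
the exponential (92 rows also meet a raw ±0.001).  Of the 26 quoted
heterogeneity-share percentages, 21 reproduce from Φ(printed mean /
printed SD) to ≤ 0.04 percentage points and are asserted at 0.1 pp.  The
five exclusions, documented as transcription/rounding defects in the
source tables rather than modelling signals: the pooled barriers share
(prints 90.57 vs computed 90.06), the pooled medium-bike-volume share
(prints 90.06 vs computed 75.44), the shared-lane medium-bike-volume and
manned shares (one duplicates another facility's value, the other's split
does not sum to 100), and the mixed-traffic manned share (duplicates the
marking value).  Narrative sign flips (a positive printed mean described
as "less likely") are treated as prose slips; shares are compared on the
printed-table magnitudes.  Similarly, a few printed interval bounds appear
transposed in the source (e.g. the pooled barriers row); the transcription
keeps them as printed and nothing downstream consumes them.

## Degenerate inputs and numerical choices

Overflow-safe likelihoods via log(1+e^η) = logaddexp(0, η), cached across
Metropolis steps; n = 0 datasets and non-binary outcomes are rejected with
row indices; single-level variables are excluded from encoding with a
warning; empty strata are skipped (default minimum stratum size 200, the
scale below which a per-facility logit with ~12 contrasts is not worth
fitting); zero-variance design columns are an error in the screen and are
pruned (logged) before stratified fits, where a level can be structurally
absent within a facility.
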