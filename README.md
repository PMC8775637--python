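# lanelogit

Bayesian random-parameter (mixed) logit models of **cyclists occupying
motorized vehicle lanes** — the risky behavior in which a rider crosses or
touches the boundary between the bike lane and the motor lanes (or, in
mixed traffic, rides more than 1.5 m from the curb).

The package is aimed at traffic-safety and injury-epidemiology researchers
who model binary risk behaviors from categorical observational covariates
(rider characteristics, road geometry, traffic conditions, environment) and
care about *unobserved heterogeneity*: two riders with identical measured
covariates need not respond to, say, a barrier dividing strip in the same
way.

## The model

Each observed rider *i* occupies the motor lane (*y_i = 1*) with probability

```
y_i ~ Bernoulli(p_i)
logit(p_i) = β_{i,0} + β_{i,1} x_{i,1} + … + β_{i,k} x_{i,k}
```

where *x_i* are treatment-coded dummies.  Coefficients declared **random**
vary across riders,

```
β_{i,k} ~ N(μ_k, Σ_k),      Σ = diag(Σ_1, …, Σ_k)
```

while the rest are fixed (β_{i,k} ≡ μ_k — the standard logit is the special
case with no random coefficients).  Estimation is fully Bayesian with vague
conjugate priors, μ_k ~ N(0, 10⁶) and Σ_k ~ InverseGamma(0.001, 0.001),
sampled by a Metropolis-within-Gibbs scheme (two chains with different
starting values).  Results are reported the way the field prints them:

- posterior mean, SD, equal-tailed 2.5%/97.5% bounds;
- **odds ratio** OR = exp(mean) per contrast;
- for random coefficients, the mixing SD √Σ_k and the **heterogeneity
  share** Φ(μ_k/σ_k) — the fraction of the rider population whose
  coefficient is positive;
- model comparison by **DIC** (D̄ + p_D), with the conventional rule that a
  difference greater than 10 may exclude the higher-DIC model.

Because the motivating field data (34,631 riders at eight sites in
Pingdingshan, China, across five bicycle-facility configurations) were
never deposited, the package ships a seeded synthetic-data generator that
reproduces the study's covariate structure and draws outcomes from a known
random-parameter logit, so every stage is testable against ground truth.
The published coefficient tables themselves are packaged
(`lanelogit.reference`) and used as regression oracles for the summary
arithmetic.

## Worked example

`examples/03_fit_random_parameter_logit.py` simulates 5,000 riders under
the published coefficient means with a random gender effect
(μ = 0.6, σ = 0.3), fits the model with two chains, and prints:

```
                    parameter   mean    sd   q2.5  q97.5  odds_ratio
                    intercept -4.417 0.307 -5.030 -3.872         NaN
        gender:male vs female  0.541 0.076  0.388  0.684       1.718
bike_type:e_scooter vs c_bike  1.613 0.195  1.261  1.985       5.018

mixing SD of the gender effect: 0.234 (95% CI 0.030-0.771; truth 0.300)
heterogeneity split: 99.0% of riders with a positive gender effect, 1.0% negative
convergence (PSRF): {'mu[gender:male vs female]': 1.002, 'sigma2[gender:male vs female]': 1.072}
```

Both 95% intervals cover their generating values (0.6 for the mean of the
gender effect, 0.3 for its SD); the odds ratio says male riders' odds of
occupying the motor lane are about 1.7× female riders' on average, and the
Φ(μ̂/σ̂) split says essentially all riders carry a positive (odds-raising)
gender effect at these estimates.  The potential-scale-reduction values
near 1 indicate the two chains agree.

The other examples cover simulation (`01`), encoding and the Pearson
collinearity screen (`02`), DIC model comparison on grouped heterogeneity
(`04`), and the per-facility stratified refits (`05`).  A thin CLI mirrors
the library: `lanelogit simulate | screen | fit | summarize | stratify |
pipeline`.

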