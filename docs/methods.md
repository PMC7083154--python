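# Methods

## The model

Each time slice is analysed cross-sectionally. The response for island *i* is
the cumulative count `s_i` of endemic taxa whose attributing event (by default
the earliest collection; optionally the type collection) happened on that
island in or before the slice's bounding year. Counts are assumed Poisson with
a log link:

    s_i ~ Poisson(λ_i)
    log(λ_i) = γ₀ + γ₁ x_i [+ γ₂ h_i] + ψ_i

`x_i` is a single standardized island covariate. Area, geological age,
maximum altitude and mean terrain ruggedness are strongly collinear across
islands (rugged islands tend to be old, high and small), so they never enter
one model together; the model grid instead crosses the four covariates with
the presence/absence of the harbor indicator `h_i`, giving eight models per
slice, and lets WAIC arbitrate.

ψ is a Gaussian-process varying intercept over islands:

    ψ ~ MVNormal(0, Γ),  Γ_ij = η² exp(−ρ² D_ij²) + 0.01 δ_ij

with squared-exponential decay in the inter-island distance `D_ij`. Because
there is exactly one observation per island per slice, the diagonal nugget is
not estimable and is fixed at 0.01 (configurable via `jitter`). Priors are
Normal(0, 10) on each regression coefficient and HalfCauchy(0, 1) on η² and
ρ² — flat over the plausible range once covariates are standardized and
distances rescaled.

Single-island endemics are excluded before modelling: a taxon confined to one
island is necessarily collected there, so it carries no information about
which island attributes attracted collectors.

### Distances and covariates

* Distances are great-circle (haversine, Earth radius 6371 km) and by default
  divided by the maximum pairwise distance, so `max D_ij = 1`. This makes the
  HalfCauchy(0, 1) prior on ρ² weakly informative for any archipelago extent,
  at the cost that posterior ρ² values are only meaningful relative to the
  rescaled metric — they are not comparable across datasets or to analyses
  using kilometres.
* Covariates are z-scored with the sample (n−1) standard deviation. Island
  areas are strongly right-skewed; `log_area=True` takes the natural log
  before standardizing. The harbor indicator is never standardized.
* Year comparisons are inclusive (`event year ≤ slice bound`). Records with a
  missing event year are dropped from panels with a logged warning rather
  than an error, since historical tables often lack a date for a few taxa.

### Count attribution

A taxon counts only toward the island of its attributing event, not toward
every island in its modern distribution: the quantity being modelled is where
collecting happened, not where the taxon lives. The `basis` switch
(`earliest`/`type`) selects which event attributes the taxon.

## Sampling

The posterior is sampled with adaptive blockwise random-walk Metropolis. The
parameter space is small (≤ 14 dimensions: 2–3 coefficients, two GP
hyperparameters, 9 island effects), where random-walk Metropolis is simple,
dependency-free and fast; the log posterior is exposed (`DiscoveryCountModel.
_log_posterior` plus the public `log_likelihood`/`log_prior`) so a
gradient-based sampler can be substituted.

Numerical choices:

* η² and ρ² are sampled as logs with the Jacobian correction, which enforces
  positivity without rejections and symmetrizes their skewed conditionals.
* Four blocks per sweep: (1) the regression coefficients jointly; (2)
  (log η², log ρ²); (3) ψ jointly, with the proposal pre-multiplied by the
  current Cholesky factor of Γ so its shape tracks the GP; (4) a translation
  along the γ₀/ψ ridge (γ₀ → γ₀ + e, ψ → ψ − e). The intercept and the
  island effects are separated only by the prior, so without the ridge move
  the chain mixes very slowly in that direction.
* Each block's scalar proposal scale adapts every 50 iterations toward a
  0.234 acceptance rate, with a decaying step (Robbins–Monro style).
  Warmup equals the number of retained draws; adaptation is frozen at the end
  of warmup so the retained chain is a valid Markov chain.
* Initialization: coefficients and log-hyperparameters near zero, ψ near
  zero, jittered per chain from the chain's own seeded generator; if the log
  posterior is not finite the draw is retried (up to 100 times).
* Chains are seeded as `default_rng([seed, chain])`, so runs are bit
  reproducible for a given seed and chain count.
* A prior-only mode disables the likelihood term; it is used to verify that
  the sampler reproduces Normal(0, 10) and HalfCauchy(0, 1) quantiles.

Convergence is summarized with split R-hat and effective sample size
(computed by arviz); a warning is emitted if any R-hat exceeds 1.05. On
9-island data, 2 chains × 1000 draws give R-hat ≲ 1.05 and ESS of order
50–200; summaries intended for reporting (as in the README example) use
4000 draws.

## Model evaluation

* WAIC uses the pointwise definition: `lppd_i = log mean_d exp(loglik_di)`,
  `p_i = Var_d(loglik_di)` with the unbiased (n−1) variance (the standard
  pointwise-variance estimator), `WAIC = −2 Σ_i (lppd_i − p_i)`. A standard
  error is computed from the pointwise elpd spread but is not used for
  ranking.
* Akaike weights are `exp(−Δ/2)` normalized over the compared set; reports
  round WAIC and Δ to one decimal and weights to two, matching the usual
  presentation of such tables. Comparisons refuse to mix time slices.
* The island correlation matrix is rebuilt from the posterior *medians* of
  η² and ρ² (η²'s posterior is strongly right-skewed, so means are
  misleading), then normalized: `R_ij = Γ_ij / √(Γ_ii Γ_jj)`.
* Posterior predictive curves report the median of
  `λ(x) = exp(γ₀ + γ₁ x + γ₂ h)` over draws with a central equal-tailed 80%
  interval (10%–90% quantiles), separately per harbor stratum. By default ψ
  is fixed at its prior mean 0 — a "new island" interpretation; with
  `psi_mode="sample"` one ψ is drawn per posterior draw from
  MVNormal(0, Γ(η², ρ²)) instead, which widens the bands by the full
  island-effect uncertainty.

## The synthetic generator

`SyntheticConfig` defaults encode the study conditions the package is built
around: 9 islands, 2 of them with harbors, 91 endemic taxa. Specifics:

* Covariates are drawn from a multivariate log-normal whose log-scale
  correlation matrix has altitude–age–ruggedness pairwise +0.8 and
  altitude–area −0.7 (remaining area pairs −0.6; the matrix is verified
  positive definite at construction, and an infeasible user matrix is
  rejected naming the offending pair).
* The count-model truth is γ₀ = 2.0, γ₁ = 0.6 (on standardized ruggedness),
  γ₂ = 0.8, η² = 0.3, ρ² = 2.0 on max-rescaled distances — chosen to give
  per-island cumulative counts from a few to a few tens, the scale of a
  ~90-taxon endemic flora over 9 islands.
* Description lags come from a two-component mixture: with probability 0.8 a
  prompt gamma component (shape 1.2, mean 28.75 years, capped below a
  century) and with probability 0.2 a century-scale rediscovery component
  (101 + Exponential(29) years). A single gamma or log-normal with mean 49
  cannot place 20% of its mass above 100 years; real lag distributions are
  bimodal because early collections are often described only when a later
  monographer revisits the herbarium. The mixture has mean 49 years and a
  20% century tail.
* Collector identities use geometric rank weights with ratio 0.74538 over 31
  names, solved so the five most prolific collectors are expected to hold
  77% of first records; describing authors use a similar pool of 20.
* 85% of earliest-collection years fall before 1900 (uniform within the
  pre-/post-1900 ranges), and earliest ≤ type ≤ publication holds by
  construction.
* Island attribution of records follows the same log-linear intensity λ as
  the count model (with the identical ψ substream for a given seed), so a
  record table and a count panel generated from one seed describe the same
  collecting process — harbor and rugged islands accumulate more records.
* Cumulative panels are produced by thinning each island's final Poisson
  count with a monotone discovery-probability schedule (default 0.65 … 1.0
  over the six slices), which matches the model's per-slice cross-sectional
  likelihood; no attempt is made to simulate a mechanistic discovery process
  through time.
* All randomness flows from one seed through named substreams (islands, psi,
  counts, records), so stages can be regenerated independently.

What the generator does **not** emulate: real geography (coordinates are
uniform in a 3° box), climate or any temporal covariate, taxonomic name
changes, multi-collector specimens, or collector effort varying across
islands independently of the modelled covariates. Passing the recovery and
ranking tests therefore shows the estimator is calibrated *under the model's
own assumptions*; it does not certify the model against misspecified real
archipelagos.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run at sizes chosen to exercise
the statistics meaningfully while staying comfortably fast on one CPU:
interval-calibration uses 100 (suite) / 50 (script) replicate 9-island
datasets at 800 draws × 2 chains; the harbor-ranking check uses 20
replicates at 1000 draws; prior recovery uses 10,000 draws; the WAIC oracle
uses 200-draw × 9-observation matrices. The full 48-model grid runs at 1000
draws × 2 chains.

## Known limitations

* Nine observations per slice is very little data; posteriors for η² and ρ²
  are prior-dominated and their absolute values should not be
  over-interpreted (and depend on the distance rescaling).
* Slices are analysed independently; there is no joint spatio-temporal
  model, so period-to-period comparisons of parameters are informal.
* Random-walk Metropolis yields modest effective sample sizes per draw;
  for publication-grade intervals increase `n_draws` (4000+) or plug the
  exposed log posterior into a gradient-based sampler.
* WAIC on 9 observations has large sampling noise; Δ values within ~2 should
  be read as "comparable support", which is also how the weights present it.
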