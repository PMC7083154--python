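# island-discovery

Tools for analysing the history of botanical species discovery across island
archipelagos from specimen-record tables: who collected what, where and when;
how long taxa waited between first collection and valid description; and which
island characteristics — natural (area, geological age, maximum altitude,
terrain ruggedness) or man-made (the presence of a major harbor) — best explain
where collecting effort accumulated.

The package is aimed at biodiversity informaticians and historical botanists
working with herbarium data at the scale of a small archipelago (tens of
islands, tens to hundreds of endemic taxa), where classical
occupancy/accumulation approaches run out of data and a hierarchical Bayesian
model can still say something useful.

## The model

For each time slice, the cumulative number of taxa attributed to island *i* is
modelled as

```
s_i ~ Poisson(λ_i)
log(λ_i) = γ₀ + γ₁ x_i [+ γ₂ h_i] + ψ_i
ψ ~ MVNormal(0, Γ),   Γ_ij = η² exp(−ρ² D_ij²) + 0.01 δ_ij
γ_j ~ Normal(0, 10),  η², ρ² ~ HalfCauchy(0, 1)
```

where `x_i` is one standardized island covariate (area, age, altitude or mean
terrain ruggedness — they are strongly collinear, so one enters at a time),
`h_i` an optional harbor indicator, `D_ij` the (max-rescaled) haversine
distance between islands, and ψ a Gaussian-process varying intercept that
absorbs spatial autocorrelation in collecting effort. The eight resulting
models per time slice (4 covariates × harbor on/off, GP always included) are
ranked by WAIC with Akaike weights.

The posterior is sampled by an adaptive blockwise random-walk Metropolis
sampler (the parameter space is at most 14-dimensional); the log posterior is
exposed so a gradient-based sampler can be substituted.

## Worked example

```python
import numpy as np
import island_discovery as idisc

# synthetic archipelago at the default study conditions:
# 9 islands, 2 harbors, 91 endemic taxa
cfg = idisc.SyntheticConfig(seed=1)
islands = idisc.generate_archipelago(cfg)
records = idisc.generate_records(cfg, islands)

lag = idisc.lag_summary(records, thresholds=[100])
print(f"mean description lag: {lag.mean_lag:.1f} years, "
      f"{100 * lag.fraction_exceeding[100]:.0f}% over a century")

modelled = idisc.exclude_single_island_endemics(records)
panel = idisc.build_count_panel(modelled, islands)   # periods 1850..1975
model = idisc.DiscoveryCountModel.from_panel(
    panel, islands, period=1975, covariate="tri", include_harbor=True)
res = model.fit(n_draws=4000, n_chains=2, seed=3)
print(res.summary().round(2).head(5))
print(f"WAIC: {res.waic().waic:.1f}")
```

prints

```
mean description lag: 45.1 years, 15% over a century
              mean    sd  median   q10   q90  rhat     ess
parameter
gamma0        1.37  1.40    1.29 -0.14  2.88  1.01  170.91
gamma_cov     0.56  0.21    0.55  0.29  0.83  1.00   94.66
gamma_harbor  0.90  0.50    0.89  0.25  1.60  1.04   71.63
eta2          2.93  6.16    1.49  0.53  6.08  1.01  153.06
rho2          2.01  2.48    1.26  0.35  4.46  1.02   68.39
WAIC: 43.6
```

— the slope on ruggedness (`gamma_cov`) and the harbor term are both
positive: rugged islands and harbor islands accumulated more recorded taxa,
and the 80% intervals (q10–q90) exclude zero for the slope. The `eta2`/`rho2`
rows summarize the spatial covariance of the island effects.

The same pipeline runs from the shell:

```
island-discovery run-all --synthetic --out results/demo --seed 1
island-discovery report --manifest results/demo/manifest.json
```

Real data enter as two CSVs (`island-discovery run-all --records ... --islands ...`);
the column dialects are documented in `island_discovery.records`.

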