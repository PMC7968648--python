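# bymap

Bayesian spatial disease mapping of registry count panels with the
Besag–York–Mollié (BYM) model.

## The problem

Cancer registries report event counts by region, age band and calendar
period. At sub-national scale the raw counts are noisy (small populations)
and biased (registries capture only a fraction *c* of true cases, and that
fraction changes over time). `bymap` provides a tested pipeline for turning
such panels into smoothed, comparable age-standardised rates (ASRs):

1. **Indirect standardisation** — national reference age-specific rates
   `r_a` are applied to each region's interpolated age structure to give
   expected counts `E[i,p] = Σ_t Σ_a r_a · P[i,a,t]`;
2. **Completeness adjustment** — `E` is multiplied by the registry
   completeness fraction so the model's mean refers to *observed* counts;
3. **BYM smoothing** — observed counts follow

   `O[i,p] ~ Poisson(E_adj[i,p] · θ[i,p])`,
   `log θ[i,p] = α + x[i,p]ᵀβ + u_i + v_i`,

   where `u` carries an intrinsic conditional autoregressive (ICAR) prior
   on the region adjacency graph (spatially structured variation), `v` is
   an exchangeable Gaussian effect, and `x` holds standardised region-level
   covariates (urbanisation, mean years of schooling, optionally
   log-completeness). The model is fitted by an adaptive
   Metropolis-within-Gibbs sampler written for exactly this structure:
   conjugate Gibbs updates for the two precisions, graph-coloured
   element-wise Metropolis updates for the random effects;
4. **Reporting** — posterior draws of `θ` scale the reference ASR into
   region ASRs per 100,000 with 95% credible intervals (2.5th–97.5th
   percentiles), draw-wise percentage changes between intervals,
   wealth-quintile stratifications and rank tables;
5. **Diagnostics** — residual Moran's I with a permutation null, DIC, and
   split-R̂/ESS convergence summaries.

A synthetic-data generator emulates the intended study conditions — a
31-region panel of female breast-cancer events for women aged 30+, three
reporting intervals (2000–2003, 2004–2007, 2008–2010), censuses in
1996/2006/2011 and registry completeness rising from 0.22 to 0.75 — so the
whole pipeline is testable end to end without access to confidential
registry data.

## Worked example

```python
import numpy as np
from bymap import (simulate_scenario, adjust_for_completeness, run_mcmc, MCMCConfig,
                   monitor_theta, asr_from_relative_risk, summarize_draws,
                   percent_change, pearson_residuals, morans_i, compute_dic)

scen = simulate_scenario(seed=42)          # 31 regions, 3 intervals, c: 0.22 -> 0.75
e_adj = adjust_for_completeness(scen.expected, scen.covariates)
cfg = MCMCConfig(n_iter=6000, n_burnin=3000, thin=3, n_chains=2, seed=42)
draws = run_mcmc(scen.counts_observed, e_adj, scen.covariates, scen.graph, cfg)

beta = draws.stacked("beta")
print("beta:", beta.mean(axis=0).round(3), "+-", beta.std(axis=0).round(3))

region = scen.graph.region_ids[0]
for period in scen.counts_observed.periods:
    asr = asr_from_relative_risk(monitor_theta(draws, region=region, period=period),
                                 scen.reference)
    s = summarize_draws(asr)
    print(f"{region} {period}: ASR {s.mean:.1f} per 100,000 "
          f"(95% CrI {s.lo:.1f}, {s.hi:.1f})")

resid = pearson_residuals(scen.counts_observed.totals(), draws, e_adj.values)
mor = morans_i(resid, scen.graph, seed=42)
print(f"residual Moran's I = {mor.I:.3f}, p = {mor.p_value:.3f}")
```

prints

```
beta: [ 0.583 -0.328] +- [0.074 0.036]
R00 2000-2003: ASR 149.4 per 100,000 (95% CrI 143.0, 155.9)
R00 2004-2007: ASR 144.7 per 100,000 (95% CrI 139.0, 150.4)
R00 2008-2010: ASR 140.0 per 100,000 (95% CrI 134.4, 145.6)
residual Moran's I = -0.133, p = 0.487
```

The posterior means of `β` bracket the generating truth `(0.5, −0.3)`
within about one posterior sd: the sampler recovers the covariate effects
from counts that were binomially thinned down to 22–75% completeness. The
per-region ASRs are the reference ASR scaled by the smoothed relative risk,
and the non-significant Moran's I (p ≈ 0.49) says the ICAR component has
absorbed the spatial structure in the residuals.

The same pipeline is scriptable from the shell:

```sh
bymap simulate --seed 3 --n-regions 31 --out run/
bymap standardise --in run/ --out run/
bymap fit --in run/ --out run/ --seed 3
bymap diagnose --in run/ --out run/ --seed 3
bymap report --in run/ --out run/ --seed 3
```

writing tidy CSV tables (rates, changes, quintiles, ranks, residuals) and
JSON reports into `run/`.

## Layout

- `src/bymap/containers.py` — validated data containers (adjacency graph,
  population grid, event/covariate panels, reference rates) with tidy
  CSV/JSON serialisation
- `src/bymap/synthetic.py` — lattices, populations, covariates, generative
  BYM counts and binomial thinning
- `src/bymap/demography.py` — intercensal interpolation, reference rates,
  expected counts, completeness adjustment, ASR scaling
- `src/bymap/model.py` — BYM likelihood, ICAR prior, the MCMC sampler
- `src/bymap/diagnostics.py` — Moran's I, DIC, convergence summaries
- `src/bymap/reporting.py` — summaries, percentage change, quintiles, ranks
- `src/bymap/validation.py` — oracle/calibration experiments
- `src/bymap/cli.py` — the `bymap` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
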