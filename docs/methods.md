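# Methods

## Model

Counts `O[i,p]` of events in region `i` during reporting interval `p`
(pooled over age bands) are modelled as

    O[i,p] ~ Poisson(E_adj[i,p] * theta[i,p])
    log theta[i,p] = alpha + x[i,p]' beta + u_i + v_i

`theta` is the relative risk smoothing the raw standardised ratio `O/E`.
The decomposition of cross-region variation follows the Besag–York–Mollié
convention: `u` is spatially structured, `v` exchangeable.

* `u | tau_u` carries the intrinsic conditional autoregressive (ICAR)
  prior: log-density `((n-k)/2) log tau_u - (tau_u/2) * sum_{i~j}
  (u_i - u_j)^2` over unordered neighbour pairs, with `k` the number of
  graph components (the prior's rank deficiency). It is improper and
  translation-invariant within each component; identifiability is restored
  by recentring `u` to component-wise mean zero after every sweep.
* `v_i ~ Normal(0, 1/tau_v)` i.i.d.
* `alpha, beta ~ Normal(0, 10^2)` on covariates standardised to mean 0 /
  sd 1 across all region-period cells (the centring/scaling map is stored
  with the draws). Standardisation also makes the posterior relative risks
  exactly invariant to shifting a raw covariate by a constant.
* `tau_u, tau_v ~ Gamma(0.5, 0.0005)`, the common disease-mapping default
  for BUGS-style BYM models; both hyperpriors are configurable.

The Poisson likelihood omits the constant `log O!` everywhere, including in
the DIC, so deviances are comparable across models but not across software
that keeps the constant. Cells with `E_adj = 0` are excluded from the
likelihood with a warning; a positive count against `E_adj = 0` is
impossible under the model and aborts initialisation.

### Registry completeness

Completeness `c[i,p]` (fraction of true events captured) enters as a
multiplicative offset: `E_adj = E * c`, so the modelled mean refers to the
*observed*, under-registered counts and the Poisson likelihood keeps
integer data. Two alternatives are provided for comparison: dividing the
counts by `c` (`inflate_counts`) produces non-integer counts the likelihood
rejects by contract, and a `log_completeness` design column lets the data
estimate a free under-reporting elasticity instead of fixing it at 1. The
wealth index is never a regression column — it is a stratifier only.

### Sampler

Metropolis-within-Gibbs, written for this structure:

* conjugate Gibbs draws for `tau_u` (shape `a + (n-k)/2`, rate `b +
  (1/2) sum_{i~j} (u_i-u_j)^2`) and `tau_v` (shape `a + n/2`, rate
  `b + (1/2) sum v_i^2`);
* random-walk Metropolis for `alpha` and each `beta_k`;
* element-wise random-walk Metropolis for `u` in graph-colouring blocks:
  within a colour class no two regions are adjacent, so their full
  conditionals are mutually independent and the whole class can be
  proposed, evaluated and accepted as a vector without breaking detailed
  balance. `v` updates are vectorised the same way (all regions at once);
* after each sweep `u` is recentred; for a connected graph the removed mean
  is added to `alpha`, leaving the linear predictor untouched (for a
  multi-component graph the shift is component-specific and is simply
  subtracted — the classic BUGS-style constraint-by-recentring);
* proposal scales adapt every 50 sweeps during burn-in towards 35–40%
  acceptance and are frozen afterwards, so the post-burn-in chain is a
  fixed-kernel Markov chain;
* chains are seeded from spawned `SeedSequence` children of the config
  seed: identical configs reproduce draws bit for bit.

Initial values are data-driven (intercept at the pooled log standardised
ratio, effects split from per-region residual log-ratios) to avoid the
slow-start pathology of starting the random effects at zero, where the
Gibbs step would immediately drive the precisions to very large values.

Defaults: 3 chains, 20,000 iterations, 10,000 burn-in, thinning 5.

## Demography

* **Intercensal interpolation** is geometric: `P_t = P_a (P_b/P_a)^((t-a)/
  (b-a))`, exact at censuses and equivalent to log-linear interpolation;
  extrapolation beyond the last census carries the final intercensal
  growth rate forward for at most 5 years. Interpolating from a zero
  population towards a positive one has no defined growth rate and raises.
* **Reference rates** are national age-specific rates of a reference year
  (counts pooled over regions / national population per band). The
  standard-population weights default to that same national population, so
  the implied reference ASR is the national crude rate of the reference
  year per 100,000; region ASRs are reported as `theta` times this
  reference ASR rather than recomputed age-by-age, which keeps the rate
  scale and the smoothing on the same footing.
* **Expected counts** sum `rate_a * P[i,a,t]` over the age bands and the
  calendar years pooled by each interval (4, 4 and 3 years for the default
  periods); a `drop_years` mask removes reporting years with no data
  collection (e.g. a missing registry year) from the person-year total so
  `E` stays comparable with `O`.

## Synthetic data

The generator emulates the intended study conditions; its defaults are the
study dimensions, not tuning knobs: 31 regions, 11 five-year age bands
(30–34 … 80+), intervals 2000–2003 / 2004–2007 / 2008–2010, censuses
1996/2006/2011, registry completeness rising linearly from 0.22 to 0.75,
about 300,000 women aged 30+ per region, annual growth 0.5–2.5%, covariate
effects `beta = (0.5, -0.3)` on standardised urbanisation and schooling,
spatial effect sd 0.4 and exchangeable sd 0.15. The age-specific rate
template rises from age 30 and plateaus in the 60s, scaled so the national
reference ASR lands near 50 per 100,000 — the order of magnitude of a
middle-income breast-cancer registry.

Lattices: row-major rectangles with rook adjacency (the 31-region default),
rings, or Delaunay triangulations of random points ("random-planar"); all
are connected by construction. The wealth index is a standard-normal draw
shrunk towards the neighbour mean (weight 0.7), so wealth quintiles form
spatially coherent blocks; urbanisation and schooling are built around it,
making the regression columns correlated with the spatial field, as in
real panels. The spatial truth is drawn from the ICAR distribution on its
proper subspace (Laplacian eigenvectors with positive eigenvalue) and
rescaled to the target sd.

Under-registration is binomial thinning of the true counts with the
completeness fraction — an observation model, deliberately matching the
offset convention used at fit time.

What the generator does *not* emulate: age-specific relative risks (risk
varies by region, not by age within region), migration between regions,
registry duplicates or miscoding, and covariate measurement error. Passing
tests therefore demonstrate correctness of the machinery under the stated
generative model, not robustness to those real-data pathologies.

## Diagnostics

* **Residuals**: Pearson residuals `(O - mu_hat)/sqrt(mu_hat)` on
  posterior-mean fitted values, averaged over periods; signed deviance
  residuals are available as an alternative.
* **Moran's I**: `I = (n/S0) * sum w_ij z_i z_j / sum z_i^2` with binary
  symmetric weights by default (row-standardised optional), expectation
  `-1/(n-1)`, and a two-sided permutation p-value with the add-one rule
  (`p >= 1/(n_perm+1)`, default 999 permutations). The validation
  experiment that exercises this on fitted residuals uses longer chains
  (6,000 iterations) than raw coverage checks, because Monte-Carlo error in
  the plug-in posterior mean feeds directly into the residuals and
  inflates the test's size; the experiment also keeps truth, data, sampler
  and permutation random streams strictly separate — re-using one stream
  measurably biases the permutation null.
* **DIC**: `dbar + p_d` with `p_d = dbar - d_hat`, `d_hat` evaluated at the
  posterior means of `alpha, beta, u, v` (plug-in focus at the relative-
  risk level, the BUGS convention).
* **Convergence**: rank-normalised split-R̂ and bulk ESS via `arviz`;
  parameters with R̂ > 1.05 are flagged. Note that split-R̂ of two
  bit-identical stationary chains is close to, but not exactly, 1 (the
  half-chains still differ); the tests assert closeness.

## Reporting conventions

* Credible intervals are 2.5th–97.5th percentiles with numpy's linear
  order-statistic interpolation.
* Percentage change between intervals is computed draw-wise (ratio first,
  summarise second), which yields the asymmetric intervals characteristic
  of skewed rate posteriors; `point` mode applies the identical formula to
  two point estimates and reproduces published-table arithmetic.
* Quintiles: regions sorted ascending by wealth index (ties broken by
  region id), cut into five groups with remainders allocated to the
  poorest quintiles first — 31 regions give sizes (7, 6, 6, 6, 6).
  Quintile rates are unweighted means of member-region rates per draw;
  population weighting is an option.
* Ranks are dense (ties share a rank) with a deterministic tie-broken
  display rank that is always a permutation.

## Design choices made where the design was open

* The three reporting intervals are fitted independently (each with its own
  `alpha, u, v`), matching per-interval reporting; a joint fit sharing the
  random effects across periods is available (`periods="joint"` in the CLI,
  or simply passing the full panel to `run_mcmc`) and is what the
  parameter-recovery validation uses, since identifying time-varying
  covariate effects requires the within-region contrast.
* Age bands are 5-year bands from 30–34 to 80+; configurable.
* The completeness offset (not count inflation) is the default adjustment.
* ICAR is implemented as the improper pairwise-difference prior with rank
  correction and recentring, not a proper CAR with an autocorrelation
  parameter.

## Numerical sizes used in validation

The quadrature oracle uses 20,000 retained draws (thinning 5); interval
calibration uses 200 replicates of a 16-region lattice with 2,000 retained
draws each; the Moran null experiment uses 50 replicates; the recovery
check uses the full 31-region, 3-period panel at the default sampler
settings. These sizes keep each experiment to minutes on one CPU while
leaving the Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* DIC values are only comparable under this package's constant-omission
  convention.
* The recentring step treats the `alpha` prior as locally flat when
  absorbing the mean of `u`; with sd-10 priors the approximation error is
  negligible but it is an approximation.
* No spatio-temporal interaction: a region's spatial effect is constant
  within a fit.
* Credible-interval calibration is demonstrated for the generative model's
  own conditions; under model misspecification (e.g. overdispersion beyond
  `v`) intervals may undercover.
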