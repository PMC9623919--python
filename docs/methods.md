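# Methods

## Problem and model

`stcar` estimates small-area mortality risk from a panel of observed death
counts `O_it` in N areal units (municipalities) over T years. Raw
standardized mortality ratios `SMR_it = O_it / E_it` are unstable where
expected counts `E_it` are small — a handful of deaths per year in most
municipalities — so the package fits a Bayesian spatio-temporal conditional
autoregressive (CAR) Poisson model that borrows strength across neighbouring
areas and adjacent years:

```
O_it ~ Poisson(lambda_it)
log lambda_it = log E_it + a + x_it' beta + phi_it
phi_1 ~ N(0, tau^2 Q(W, rho_s)^{-1})
phi_t | phi_{t-1} ~ N(rho_t phi_{t-1}, tau^2 Q(W, rho_s)^{-1}),  t = 2..T
```

with the Leroux precision `Q(W, rho_s) = rho_s (diag(W1) - W) + (1 - rho_s) I`
on a binary queen-contiguity adjacency `W` (optionally augmented with
explicit edges, e.g. ferry links for island municipalities). `rho_s` and
`rho_t` interpolate between independence (0) and strong spatial/temporal
autocorrelation (1); `tau^2` is the innovation variance of the process.

Priors: `tau^2 ~ Inverse-Gamma(1, 0.01)`, `rho_s, rho_t ~ Uniform(0, 1)`,
and `N(0, 1e5)` on the intercept and each regression coefficient. The model
itself states no coefficient prior; a vague proper Gaussian is the
conventional choice for this family and leaves the likelihood dominant.
Sensitivity reruns with `Inverse-Gamma(0.5, 0.005)` and
`Inverse-Gamma(1, 0.05)` on `tau^2` are built in.

## Standardization

Expected deaths use indirect standardization with mean reference rates:
for each sex x five-year-age-group stratum k, the rate is the mean annual
reference deaths divided by the mean annual reference population over the
study years; `E_it = sum_k rate_k * population_itk`. Applying the reference
population's own rates back to it reproduces the pooled death total within
rounding, so the pooled reference SMR is 1 by construction.

Covariates are z-scored over the pooled region-year sample before fitting,
so each `exp(beta_j)` reads directly as a relative risk per one standard
deviation; the raw-scale SD is reported next to each RR. The
facility-distance covariate is the great-circle (haversine, radius
6371.0 km) distance from a region's representative point to the nearest
active facility; at prefecture scale the difference from a true geodesic is
far below the positional uncertainty of a "representative point".
Covariates surveyed less often than annually are filled by carrying the
last observation forward; one-off census covariates are held constant over
all years.

## Screening

Before the spatial model, candidate covariates pass through a non-spatial
offset-Poisson GLM (statsmodels IRLS, deviance tolerance 1e-8, Wald 95%
intervals) and stepwise VIF elimination: while any variance inflation
factor `1/(1 - R^2_j)` exceeds 5, the single worst column is dropped and
VIFs recomputed (ties break toward the earlier column, making the procedure
deterministic). The elimination log records every drop so reruns are
auditable.

## Sampler

Inference is Metropolis-within-Gibbs, written from scratch. One sweep:

1. **Coefficients** — per-coordinate Gaussian random-walk Metropolis on
   `a, beta_1..p` against the exact Poisson likelihood.
2. **Translation move** — a joint proposal `a -> a + d`, `phi -> phi - d`
   (symmetric Gaussian `d`). The likelihood depends on `a` and `phi` only
   through their sum, so the acceptance ratio involves only the CAR prior
   and the coefficient prior; because the Laplacian annihilates constants,
   `Q 1 = (1 - rho_s) 1` and the ratio has closed form. This is a plain
   Metropolis move on the joint posterior — the model has no sum-to-zero
   constraint and `phi` is never deterministically re-centred — added
   because the intercept/effect-mean direction is only weakly identified
   and otherwise mixes far too slowly for practical chain lengths.
3. **Effects** — element-wise random-walk Metropolis over all `phi_it`.
   Cells are partitioned into conditionally independent blocks (a proper
   colouring of the spatial graph crossed with year parity: two cells
   interact in the joint Gaussian precision only if they are spatial
   neighbours in the same year or the same/adjacent region in an adjacent
   year). Each block updates as one vectorised proposal, exactly
   equivalent to one-at-a-time updates.
4. **tau^2** — exact conjugate draw from
   `IG(shape + NT/2, scale + S/2)`, where `S` is the CAR quadratic form.
5. **rho_t** — exact Gibbs draw from its Gaussian full conditional
   (mean `sum_t phi_{t-1}'Q phi_t / D`, variance `tau^2 / D`) truncated to
   (0, 1); degenerate `D = 0` falls back to the uniform prior.
6. **rho_s** — random-walk Metropolis with target
   `(T/2) log det Q(rho_s) - S/(2 tau^2)`; the log-determinant is
   `sum_k log(rho_s lambda_k + 1 - rho_s)` over the Laplacian eigenvalues,
   computed once at graph construction. Proposals outside (0, 1) are
   rejected, which is equivalent to the truncated prior.

Proposal scales (per scalar and per effect cell) adapt in batches of 50
sweeps toward 44% acceptance during burn-in only; adaptation freezes at the
end of burn-in, so the retained chain is a fixed-kernel Markov chain.
Initialisation: `a = log(sum O / sum E)`, `beta = 0`, `phi = 0`,
`tau^2 = 0.01`, `rho_s = rho_t = 0.5`; chain c uses seed `base + c`.
Retained draws per chain are `(iterations - burn_in)/thin`, and fitted
means `mu_it` are stored at the same thinning.

Numerical details: `log1p`/`expm1` forms in all acceptance ratios;
truncated-normal draws by inverse-CDF with a clamp when the window's mass
is numerically zero; `rho = 1` is rejected up front because the Leroux
precision is singular there.

## Diagnostics

Convergence is monitored with the classic Gelman–Rubin potential scale
reduction factor `sqrt(((n-1)/n W + B/n)/W)` per scalar parameter (values
below 1.1 taken as converged) plus trace export for visual checks.
Residual spatial structure is checked with Moran's I
(`I = N/sum w_ij * sum w_ij z_i z_j / sum z_i^2`, binary weights by default,
row-standardised optional) with a two-sided permutation test over region
labels, +1-corrected, 9,999 permutations by default and exact enumeration
available for up to 8 regions. Residuals are `O_it` minus the posterior
mean fit of a single chain, per year (Pearson scaling optional).

## Posterior summaries

* modeled SMR: posterior median of `mu_it / E_it` over pooled draws;
* global trend: `sum_i median-fit_it / sum_i E_it` (expectation-weighted so
  tiny municipalities do not dominate), with the unweighted across-region
  median also emitted because either aggregate is defensible;
* regional disparity: across-region IQR of modeled SMR per year
  (linear-interpolation quantiles), raw and x100;
* exceedance probability: share of pooled draws with modeled SMR above a
  threshold (default 1.0);
* RR per SD: `exp` of the coefficient posterior median and 2.5/97.5
  percentiles, with the raw-scale SD alongside;
* between-year change: per-region difference of modeled SMR and its mean.

## Synthetic study areas

The generator emulates a prefecture like Hokkaido at the published scale:
a 14x14 queen lattice minus 8 cells (188 regions) observed 2010-2020, with
optional detached island cells reconnected by ferry edges. Populations are
log-uniform in (1,000, 100,000) with a fixed ageing age pyramid and a
-0.5%/year drift; stratum death rates rise exponentially with age band
(x1.3 male), scaled to a pooled crude rate of 5.3e-4 — together these put
the median expected deaths near 4-6 per municipality-year, matching the
published municipal medians. Default covariates mirror the screened
variable set (distance to the nearest of ~12 synthetic facilities,
time-varying hospital counts, fixed socioeconomic shares) with a shared
regional factor inducing realistic collinearity, and per-SD log-RRs of
0.06/-0.10/0.12/0/-0.04 — magnitudes like those reported for
healthcare-accessibility covariates. Effects are drawn exactly from the
CAR prior (Cholesky of Q) with defaults `tau^2 = 0.3`, `rho_s = 0.8`,
`rho_t = 0.7`.

What the generator does not emulate: real geography and travel networks,
facility openings/closings, population migration between regions,
overdispersion beyond the model's own random effects, and reporting
artefacts. Passing recovery tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
their violation.

## Validation scale

The test suite validates the sampler at sizes chosen to keep a full run in
minutes on one CPU: parameter recovery uses a 10x10 lattice, T = 11,
E ~ 20, truth `(a, beta_1, beta_2, tau^2, rho_s, rho_t) =
(0.1, 0.2, -0.15, 0.3, 0.8, 0.7)`, 20 replicates of 2 chains x 8,000
iterations (burn-in 3,000, thin 10), requiring 95% credible-interval
coverage of every parameter in at least 80% of replicates, mean beta bias
below 0.05, and PSRF below 1.1 throughout. The independence-limit check
(`rho_s = rho_t = 0` vs a separately written iid-random-effects sampler)
runs on a 5x5 lattice; prior-recovery and full-conditional checks run on
3x3 lattices against dense Gaussian algebra. `scripts/acceptance.py` runs
the complete pipeline on the default 188-region synthetic prefecture with
3 chains x 12,000 iterations (burn-in 2,000, thin 10).

## Known limitations

* The intercept and the mean of `phi` are jointly identified only through
  the prior; the translation move makes this direction mix, but the
  marginal posterior of `a` alone is intrinsically wide.
* Element-wise effect updates (even blocked by colour) mix more slowly
  than a well-tuned joint update would; very long panels may need longer
  chains.
* `rho_s = 1` (intrinsic CAR) is outside the supported parameter space.
* The Poisson likelihood has no overdispersion term beyond `phi`.
* Moran's I uses the binary-weight normalisation by default; published
  analyses sometimes row-standardise, which is available but changes the
  statistic's scale.
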