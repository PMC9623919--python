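# stcar

Bayesian spatio-temporal disease mapping for small-area mortality panels.

Epidemiologists comparing mortality across municipalities face a classic
problem: the standardized mortality ratio `SMR_it = O_it / E_it` — observed
over expected deaths — is wildly unstable where populations are small, and
most municipalities record only a handful of deaths a year. `stcar` is a
tested, reusable pipeline for the standard remedy: a conditional
autoregressive (CAR) Poisson model that smooths risk across neighbouring
areas and adjacent years, producing stabilised "modeled SMR" surfaces,
covariate relative risks, exceedance-probability maps and regional-disparity
trends of the kind used in prefecture-scale stroke-mortality studies.

## Model

For region *i* = 1..N and year *t* = 1..T:

```
O_it ~ Poisson(λ_it)
log λ_it = log E_it + a + x_it'β + φ_it
φ_1 ~ N(0, τ² Q(W, ρ_S)⁻¹)
φ_t | φ_{t−1} ~ N(ρ_T φ_{t−1}, τ² Q(W, ρ_S)⁻¹)
```

with the Leroux precision `Q(W, ρ_S) = ρ_S (diag(W1) − W) + (1 − ρ_S) I` on
a binary queen-contiguity adjacency `W` (island regions can be wired to the
mainland with explicit "ferry" edges). Priors:
`τ² ~ Inverse-Gamma(1, 0.01)`, `ρ_S, ρ_T ~ Uniform(0, 1)`, `N(0, 10⁵)` on
`a` and `β`. Inference is Metropolis-within-Gibbs written from scratch
(exact conjugate draws for `τ²` and `ρ_T`, Metropolis for the rest; see
`docs/methods.md`). Expected deaths `E_it` come from indirect
standardization with sex × five-year-age-group reference rates; covariates
are z-scored so each `exp(β_j)` is a relative risk per one SD.

The pipeline stages, each its own module:

| stage | module | what it does |
|---|---|---|
| adjacency | `stcar.region_graph` | queen contiguity from GeoJSON/edge lists, Leroux precision algebra |
| standardization | `stcar.standardization` | reference rates, expected deaths, SMR, facility distances, LOCF |
| screening | `stcar.screening` | offset-Poisson GLM, stepwise VIF elimination (threshold 5) |
| inference | `stcar.model` | the spatio-temporal CAR sampler |
| diagnostics | `stcar.diagnostics` | Gelman–Rubin PSRF, Moran's I permutation tests, residuals |
| summaries | `stcar.summaries` | modeled SMR, trends, IQR disparity, RR per SD, exceedance, sensitivity reruns |
| synthetic data | `stcar.synthetic` | prefecture-scale generator with known ground truth |
| orchestration | `stcar.cli` | `stcar simulate / screen / fit / run-all ...` |

## Worked example

Simulate a small synthetic study area with known truth, fit the model, and
read off the relative risks:

```python
import numpy as np
from stcar import MCMCConfig, PriorSpec, run_mcmc, modeled_smr, rr_per_sd, psrf_table
from stcar.synthetic import SimulationSpec, simulate_panel

spec = SimulationSpec(rows=8, cols=8, n_remove=0, n_islands=0, seed=1)
panel, truth, extras = simulate_panel(spec)

config = MCMCConfig(iterations=6000, burn_in=1000, thin=10, chains=2, seed=1)
samples = run_mcmc(panel, extras["graph"], PriorSpec(), config)
print(f"max PSRF: {psrf_table(samples).max():.3f}")
print(rr_per_sd(samples, extras["covariate_sds"]).round(3).to_string(index=False))
```

Output:

```
max PSRF: 1.024
           variable    rr  cr_low  cr_high     sd
       distance_psc 1.071   1.004    1.140 23.896
emergency_hospitals 0.899   0.859    0.941  0.996
  general_hospitals 1.156   1.108    1.213  1.019
            clinics 0.995   0.950    1.046  1.016
      college_ratio 1.009   0.964    1.059  0.972
```

Every chain converged (PSRF ≤ 1.1). The fitted relative risks recover the
generating values: the synthetic truth used per-SD log-RRs of +0.06 for
facility distance (`e^0.06 ≈ 1.062` vs fitted 1.071), −0.10 for emergency
hospitals (`e^-0.10 ≈ 0.905` vs 0.899) and +0.12 for general hospitals
(`e^0.12 ≈ 1.127` vs 1.156); the null covariate (`clinics`) sits at 0.995
with a credible interval straddling 1. The `sd` column is the raw scale of
each covariate (km for distance), so "RR 1.071 per 23.9 km" is the
substantive reading.

The same run from a shell, with CSV/GeoJSON artefacts and a manifest:

```
stcar run-all --seed 1 --out results/demo
```

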