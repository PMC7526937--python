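# upmigrate

Modeling tools for the survival of adult Snake River sockeye and
spring/summer Chinook salmon during their upstream migration through the
Columbia–Snake hydrosystem, and for projecting that survival under future
climate scenarios.

Endangered Snake River sockeye and threatened Chinook salmon climb more
than a thousand kilometres past eight dams to reach their spawning grounds,
migrating during peak summer temperatures.  `upmigrate` implements the full
analysis chain a fisheries scientist needs to study how river temperature,
flow, and pre-existing anthropogenic pressures (juvenile transportation,
hatchery origin, fishery catch) combine to determine adult migration
survival — and how that survival shifts when daily temperature and flow
series are replaced by downscaled climate-scenario series:

* **Covariate construction** — reach-entry temperature and flow (windowed
  averages in the free-flowing Salmon reach), cumulative thermal load in
  degree-days accumulated dam-to-dam
  (`M_Snake = D1·(T_BON+T_MCN)/2 + D2·(T_MCN+T_ICH)/2`, plus the
  Ice Harbor→Lower Granite leg for the Salmon reach), and weekly fishery
  catch aligned to the Bonneville passage week.
* **Arrival-timing models** — day of arrival at Bonneville Dam as a
  Gaussian (sockeye) or two-component Gaussian mixture (spring/summer
  Chinook), `Pr(x|θ) = Σ_k w_k N(x; μ_{k,t}, σ_k)` with
  `μ_{k,t} = β0_k + β1_k E_{k,t}`, the annual metric `E_k` chosen by AICc
  over all monthly/bimonthly March–June means of temperature and flow.
* **Reach survival models** — penalized binomial spline models
  `S_i ~ s(T_i) + s(F_i) + s(C_i) or s(M_i) + P_i + A_i + J_i + H_i + y`
  with thin-plate-style smooths (basis dimension 4 for T and F, 3 for C and
  M), a Gaussian year random intercept, REML smoothing selection,
  all-subsets AICc selection ("simplest model within 2 AICc"), and AUC
  goodness of fit.
* **Monte-Carlo projection** — simulate arrivals → travel → survival over
  years × scenarios (historical / dry / wet) × loops, drawing model
  parameters from the fitted covariances each loop so the spread carries
  parameter uncertainty.
* **Sensitivity grids** — earlier arrival (3–14 d), temperature deltas
  (−0.8 to +2 °C), and flow factors `F = F_hist + ΔF·Fx` with a 10 m³/s
  floor.
* **Extreme-year comparison** — how often future years are as warm/dry
  (over each run's migration window) as a 2015-like reference year, via
  skew-normal fits to annual window means.
* **Synthetic data** — a first-class generator producing environmental
  scenarios, catch series, and fish cohorts with the statistical structure
  the models assume, together with the generating truth (coefficients,
  Bayes AUC) so every stage is testable without restricted tag data.

The API follows the statsmodels convention: model classes
(`ArrivalTimingModel`, `ReachSurvivalModel`) are built from data and
`fit()` returns a results object carrying estimates, covariance,
diagnostics, `summary()`, prediction, simulation, and plotting.

## Worked example

```python
import numpy as np
from upmigrate import synthetic as syn
from upmigrate.arrival import ArrivalTimingModel, annual_covariates
from upmigrate.covariates import build_design_table
from upmigrate.survival import ReachSurvivalModel

cfg = syn.default_config()
rng = np.random.default_rng(42)
env = syn.make_observed_env(cfg, rng)          # daily T/F series per site
catch = syn.make_catch_series(cfg, rng)        # weekly Zone 6 catch
fish, truth = syn.make_cohort(cfg, env, catch, rng,
                              species="sockeye", n_fish=2000)

cov = annual_covariates(env["BON"])            # Mar-Jun monthly metrics
days = np.array([f.detections["BON"].timetuple().tm_yday for f in fish])
years = np.array([f.migration_year for f in fish])
print(ArrivalTimingModel(days, years, cov, ("temp_Apr",), 1).fit().summary())

design = build_design_table(fish, env, catch, "Columbia", species="sockeye")
print(ReachSurvivalModel(design, ("T", "C"), ("J", "A"),
                         species="sockeye", reach="Columbia").fit().summary())
```

prints

```
Arrival timing model (1-component Gaussian)
n = 2000, years = 12, loglik = -6465.06, k = 3, AICc = 12936.13
component   metric    beta0   beta1  sigma  weight
   single temp_Apr 192.1477 -1.0827 6.1324  1.0000
standard errors: beta0_1=1.5644, beta1_1=0.1499, sigma_1=0.0970

Reach survival model: S ~ s(T) + s(C) + J + A + y  [sockeye/Columbia]
n = 2000, deviance = 2517.65, edf = 7.24, AICc = 2532.19, AUC = 0.692
effective df by term:
intercept   1.00
s(T)        1.72
s(C)        1.52
J           1.00
A           2.00
year        0.00
year random-intercept variance: 0.0000
```

The arrival slope says mean sockeye arrival shifts about 1.1 d earlier per
degree of April warming at Bonneville (the generating value, −1.36 d/°C,
lies inside the 95% interval ±0.29).  In the survival model, temperature
and catch smooths and the transport and age factors are retained; the
transported-fish deficit is visible directly in the cohort: at the default
calibration, transported sockeye survive the Columbia reach at roughly half
the rate of in-river migrants (≈0.30 vs ≈0.59).

The five-stage pipeline (generate → fit arrival → fit survival → project →
sensitivity/compare) is also available from the shell:

```bash
upmigrate run-all --out runs/demo --seed 7
upmigrate make-synthetic --out data/ --seed 3
upmigrate fit-arrival --species sockeye --fish data/fish_sockeye.csv \
    --env data/env_observed_BON.csv --out arrival.json
```

## Layout

| module | contents |
| --- | --- |
| `upmigrate.io` | `FishRecord`, `EnvSeries`, `CatchSeries`, reach definitions, CSV IO, gap filling |
| `upmigrate.covariates` | design-table construction, degree-days, transforms |
| `upmigrate.arrival` | AICc, arrival mixture models, metric selection, simulation |
| `upmigrate.smoothing` | low-rank thin-plate penalized spline basis |
| `upmigrate.survival` | penalized binomial GAM, dredge selection, AUC, prediction |
| `upmigrate.travel` | parameterized dam-to-dam travel-time stand-in |
| `upmigrate.projection` | Monte-Carlo scenario projection with parameter draws |
| `upmigrate.sensitivity` | arrival/temperature/flow sensitivity grids |
| `upmigrate.scenarios` | run-window means, skew-normal exceedance analysis |
| `upmigrate.synthetic` | synthetic data generator and generator truths |
| `upmigrate.pipeline`, `upmigrate.cli` | run-all driver, YAML config, `upmigrate` CLI |

See `docs/methods.md` for the modeling assumptions, default parameter
values, and known limitations.
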