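# Methods

This note documents the models implemented in `upmigrate`, the default
parameter values and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter
for reproducing results.

## Study system and data model

Adult sockeye and spring/summer Chinook salmon are detected by PIT tag at
mainstem dams as they migrate up the Columbia and Snake rivers toward the
Salmon River basin.  Survival is scored through three reaches —
Columbia (Bonneville→Ice Harbor), Snake (Ice Harbor→Lower Granite), and the
free-flowing Salmon reach (Lower Granite→terminal weir/trap) — where
"survival" is apparent survival: re-detection at or above the reach exit.
Detection efficiency at these sites is near-perfect, so apparent survival
tracks true survival closely.

Environmental conditions are daily mean temperature (°C) and flow (m³/s)
per site.  The impounded reaches are summarized by entry-day conditions at
the entry dam; the long Salmon reach by means over 7 days (Chinook) or
14 days (sockeye) from reach entry, using the Anatone gauge for temperature
and the Whitebird gauge for flow (a configuration mapping, not a
hard-coded rule, since gauge roles differ by variable there).  Missing days
in an environmental series are filled by linear interpolation for short
interior gaps (≤3 days by default; the cutoff is configuration because no
authoritative value exists) and otherwise by OLS regression on a neighboring
site fit over shared complete days.

## Cumulative thermal load

Each fish's degree-day load prior to entering a reach is the sum over
dam-to-dam legs of (leg duration in days) × (mean of the entry-day
temperatures at the leg's two dams).  This is exactly the trapezoid rule
applied to a temperature path linearly interpolated between dam-passage
snapshots — the property the test suite verifies against a brute-force
day-by-day oracle.  Because same-day traversal gives M = 0, the modeling
transform is ln(M + 1 degree-day).  Catch is cube-root transformed; both
transforms limit the leverage of the long right tails.

## Arrival-timing model

Arrival day-of-year at Bonneville is Gaussian for sockeye and a
two-component Gaussian mixture for Chinook, each component mean a linear
function of one annual environmental metric; component standard deviations
and the mixing weight p (proportion spring-run) are constant across years.
The per-year residual term of the mean model is absorbed into the component
standard deviation — with one observation layer, only one residual scale
per component is identifiable.

Fitting is direct maximum likelihood on a transformed scale (log σ,
logit p) by BFGS with random restarts (default 10 for final fits, fewer
during candidate screening).  Components are ordered so the earlier mode is
labeled "spring"; since each component is tied to its own metric, a swap
also swaps the metric assignment.  Parameter covariance is the inverse
observed information, computed by central finite differences on the natural
scale.  When a metric does not vary across years the slope is structurally
unidentifiable; it is pinned at zero and flagged, and its covariance row is
reported as NaN.

Candidate metrics are all monthly and bimonthly means of temperature and
flow at Bonneville for March–June (bimonthly = two consecutive calendar
months).  Flow metrics are expressed in units of 1000 m³/s so slope
coefficients are O(1)–O(10⁻²).  Model choice is lowest AICc, ties broken
deterministically by candidate order; the full ranking is retained.

## Reach survival model

The survival state is binomial with logit link:

    S ~ s(T) + s(F) + s(C) or s(M) + P + A + J + H + (year)

Smooths are low-rank thin-plate-style penalized splines: a radial |x−κ|³
basis on `dim` quantile-placed knots under the natural constraints, with
the wiggliness penalty positive semidefinite and its null space exactly
the linear functions; the constant is removed by column centering
(sum-to-zero identifiability), so a `dim`-basis smooth contributes
`dim − 1` coefficients of which one (linear) is unpenalized.  Basis
dimension is 4 for T and F and 3 for C and M ("knots" in the mgcv sense of
`k`), limiting flexibility where the relationship is presumed
unidirectional.

The migration-year random intercept is a ridge-penalized factor smooth
(one indicator column per year, identity penalty); its implied variance is
φ/λ_year and its effective degrees of freedom count toward model df.
Smoothing parameters are chosen by Laplace-approximate restricted marginal
likelihood (REML; a GCV alternative is available via `fit(method="gcv")`),
optimized by Nelder–Mead over log λ with the penalized IRLS solver warm
started between evaluations.  The coefficient covariance is the Bayesian
(X'WX + S)⁻¹ with φ = 1.

Rules carried into model construction: catch enters only the Columbia
reach; cumulative temperature only the Snake and Salmon reaches; population
and origin are never used for sockeye (a single, almost entirely hatchery
population); smooth covariates are combined only when all pairwise
|r| < 0.7, and a greedy prefilter drops later terms that violate the rule
against earlier ones.  Ocean age is an unordered factor with levels
{1, 2, 3+}.

All-subsets selection fits every subset of the global terms (smooths enter
whole, year always included), ranks by AICc with k = total effective df,
and selects the model with fewest terms among those within 2 AICc of the
best (ties: fewest edf, then lexicographic).  The intercept-only null model
is included in the ranking for reference.  Complete separation is detected
(diverging linear predictor or coefficients) and raised as an error rather
than silently returned.

Goodness of fit is AUC — the Mann–Whitney concordance between predicted
survival and outcome, ties counted ½ — and predictions outside the convex
hull of observed (T, F) are flagged as extrapolations.

## Travel-time stand-in

The behavioral travel-time model used with hourly river conditions in the
original analysis chain is not reimplemented.  In its place each
dam-to-dam leg draws from a two-component ("fast"/"slow" migrants)
log-normal mixture whose log-median shifts linearly with temperature and
flow at the leg entry relative to reference conditions (15 °C; a per-leg
reference flow).  With equal weights and equal log-SDs the component
medians are placed log-symmetrically, so the mixture median equals the
geometric mean of the component medians exactly; the Salmon-reach defaults
are calibrated this way to the observed medians — 39 d for sockeye
(components 33 and 46.1 d, log-SD 0.25, giving SD ≈ 12.5 vs 12.6 observed)
and 19 d for Chinook (13 and 27.8 d, log-SD 0.52, SD ≈ 16) — with
hydrosystem legs of a few days each.  Default covariate sensitivities are
mild (−0.01 log-median/°C, +2×10⁻⁵ per m³/s).  Trajectories exceeding
120 d from Bonneville are truncated and the fish flagged censored;
censored fish count as deaths in cumulative summaries, a deliberately
conservative convention.  The structural adequacy of this stand-in for any
particular real system is a stated limitation, not a claim.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Environment.**  Per-site seasonal temperature sinusoids (annual mean
  11.5–12.8 °C, amplitude 8.5–10 °C, summer peak near day 212) with AR(1)
  daily weather and a shared interannual anomaly (SD 0.8 °C — the scale of
  observed year-to-year April temperature variation); flow as baseflow plus
  a Gaussian spring-freshet pulse (e.g. Bonneville 2500 + 5000 m³/s peaked
  near day 150) with lognormal interannual variation (SD 0.18 in log).
  Climate scenarios add a baseline plus summer-bump warming that grows
  moving upstream (≈1.6 °C at Bonneville to ≈3.2 °C in the Salmon reach at
  the summer peak), shift the freshet about 10 d earlier, shrink (dry) or
  raise (wet) its peak, and reduce late-season flows — most strongly at
  Whitebird, where the sockeye run loses up to ~45% of its flow.  One
  designated year of the retrospective period is "2015-like": +2 SD
  temperature and −2 SD flow anomalies.
* **Cohorts.**  Composition matches the observation dataset: transported
  proportions 0.33 (Chinook) / 0.38 (sockeye); hatchery 0.74 / 0.99;
  ocean-age-2 0.66 / 0.89.  Arrival truths use the best-model
  coefficients of the retrospective fits: sockeye −1.36 d/°C on April
  temperature; spring Chinook −3.06 d/°C; summer Chinook +0.02 d per
  1000 m³/s April flow; mixture weight 0.4 spring, means near days
  134/159, SDs 8/10 d.
* **Survival truths.**  Logistic surfaces with a piecewise-linear-in-logit
  temperature effect broken at 15 °C (mildly positive below, steeply
  negative above) — a spline truth would blur what "recovering the
  breakpoint" means — plus reach-specific flow terms (negative freshet
  effect for Chinook in the Columbia and Salmon, strongly positive flow
  effect for sockeye in the Salmon), negative log-degree-day, catch, and
  transport effects, and a hatchery deficit for Chinook.  Intercepts and
  the sockeye transport coefficient were calibrated once, by simulation,
  so that cohort-level observed survival reproduces the reported stylized
  facts (transported vs in-river sockeye in the Columbia ≈ 0.30 vs 0.59;
  reach-level means near the observed 0.82/0.96/0.87 for Chinook and
  0.47/0.83/0.57 for sockeye) and then frozen.
* **What it does not emulate.**  No hydrologic routing or spatial
  correlation beyond the configured upstream gradient; no fallback and
  re-ascension at dams; no detection failure (apparent = true survival in
  the generator); no evolutionary change in timing.  Passing tests
  therefore demonstrate correctness of the machinery under the assumed
  statistical structure, not fidelity of any conclusion about real rivers.

The generator also exposes the Bayes AUC (concordance of the *true*
probabilities with realized outcomes), the ceiling against which fitted
model AUC is compared.

## Projection and sensitivity

Each projection loop draws one multivariate-normal parameter vector per
fitted model from the retrospective covariances (non-PSD covariances are
repaired by eigenvalue clipping, and drawn σ/p are clipped to their
domains), then simulates `n_fish_per_year` fish per year, scenario, and
species: arrival day from the (drawn) arrival model and the scenario's
annual April metrics, passage via the travel model, reach survival
Bernoulli with the year effect set to zero.  Catch, transport rate,
hatchery proportion, and age composition are bootstrapped per simulated
year from the empirical annual values of the observation cohort (a
parametric alternative was considered and rejected as adding assumptions
the data table already answers).  Cumulative survival is the product of
the three reach indicators per fish; reach survivals are simulated for all
reaches regardless of earlier death so the product law is exact.

Randomness is hierarchically seeded (master seed → loop → scenario → year
→ species), so any cell reproduces independently and sensitivity grids can
run with common random numbers — the same seeds as the base run — so grid
differences are not Monte-Carlo noise.  The default design (100 fish ×
70 years × 3 scenarios × 200 loops × 2 species = 8.4 million fish) is
enumerable in closed form; tests and the bundled pipeline run much smaller
configurations (tens of fish, a few loops and years), chosen to keep the
full suite within minutes while leaving Monte-Carlo error well below the
effects being checked.

Sensitivity axes: arrival shifted 3–14 d earlier; constant temperature
deltas −0.8…+2.0 °C; flow factors 0…1.4 applied to the scenario-minus-
historical daily flow difference with a 10 m³/s floor (temperatures taken
from the scenario series).  "As extreme as 2015" is operationalized as
≥ reference for window-mean temperature and ≤ reference for flow; both the
empirical frequency and the skew-normal fitted tail are reported because
printed frequencies could be either.

## Numerical choices and edge cases

* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); errors when n ≤ k+1.
* Penalized IRLS converges on relative change in penalized deviance
  (tol 10⁻⁸, max 100 iterations); probabilities clipped to [10⁻¹⁰, 1−10⁻¹⁰].
* REML criterion: ℓ_p(β̂) + ½log|S_λ|₊ − ½log|X'WX+S_λ|, with the
  log-pseudo-determinant accumulated blockwise (rank_j·log λ_j plus the
  fixed positive eigenvalues of each S_j); log λ is bounded to ±25.
* Spline basis columns are standardized to unit RMS with the penalty
  rescaled to compensate, purely for conditioning.
* Ties in arrival-metric selection and in dredge selection break
  deterministically (candidate order; fewest terms → fewest edf →
  lexicographic term string).
* The week convention for catch alignment is Monday-start weeks
  (configurable); multi-week catch reports are spread evenly across their
  weeks.
* Arrival days simulate as real numbers and round to integer days; cohort
  arrival days clip to day-of-year 60–330 to stay inside the generated
  environmental year.

## Known limitations

* The survival GAM charges AICc with k = effective df; exact df accounting
  differs across GAMM implementations, so selection tables agree in spirit
  rather than digit-for-digit with any other toolchain.
* With the "simplest within 2 AICc" rule, every unpenalized noise degree of
  freedom in the candidate set passes the ΔAICc < 2 screen with probability
  ≈ P(χ²₁ > 4) ≈ 4.6%, so exact-subset recovery plateaus near ~86–88% for
  a five-term candidate space regardless of implementation — an intrinsic
  property of the selection rule, visible in the selection-consistency
  test.
* The travel-time stand-in has no behavioral states and no hourly
  covariate response; projection results inherit that simplification.
* Arrival mixing weight p is pooled across years (a per-year option exists
  structurally but is not fitted by default — with component metrics
  varying by year, per-year weights are weakly identified).
* Skew-normal ML fits on very short series (<10 years) fall back to a
  moments normal and are flagged.
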