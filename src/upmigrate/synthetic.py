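"""Synthetic cohorts, environmental scenarios, and generator truths.

Everything the retrospective and prospective analyses consume can be
generated here with the statistical structure the models assume: seasonal
temperature sinusoids with a spring freshet flow pulse per site, scenario
offsets with summer-amplified warming that grows moving upstream, bimodal
(Chinook) and unimodal (sockeye) arrival distributions whose means track
annual spring metrics, stated cohort composition, travel via the stand-in
travel model, and logistic reach-survival surfaces that decline above a
15 degC breakpoint with reach-specific flow effects.

True parameter values (arrival coefficients, survival surfaces, Bayes AUC)
are returned alongside the data so recovery tests have exact targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .arrival import annual_covariates
from .covariates import align_catch, cumulative_temp, cube_root, log_degree_days, reach_conditions
from .io import REACHES, REACH_ORDER, ROUTE, CatchSeries, EnvSeries, FishRecord
from .survival import auc as _auc
from .travel import TravelTimeModel, default_travel_model

__all__ = [
    "SeasonalSite",
    "ScenarioDelta",
    "ArrivalTruth",
    "SurvivalTruth",
    "GeneratorConfig",
    "default_config",
    "make_env_scenarios",
    "make_observed_env",
    "make_catch_series",
    "make_cohort",
    "bayes_auc",
]

SITES = ("BON", "MCN", "ICH", "LGR", "ANATONE", "WHITEBIRD")


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class SeasonalSite:
    """Seasonal temperature sinusoid and freshet flow pulse for one site."""

    temp_mean: float          # annual mean, degC
    temp_amp: float           # sinusoid amplitude, degC
    temp_peak_day: float = 212.0
    temp_noise_sd: float = 0.5
    flow_base: float = 2500.0   # m3/s
    flow_peak: float = 5000.0   # freshet peak above base, m3/s
    flow_peak_day: float = 150.0
    flow_width: float = 35.0    # gaussian freshet width, days
    flow_noise_sd: float = 0.05  # multiplicative daily noise

    def temperature(self, doy, anomaly=0.0):
        phase = self.temp_peak_day - 365.25 / 4.0
        return (
            self.temp_mean
            + self.temp_amp * np.sin(2 * np.pi * (doy - phase) / 365.25)
            + anomaly
        )

    def flow(self, doy, log_anomaly=0.0):
        pulse = self.flow_peak * np.exp(-0.5 * ((doy - self.flow_peak_day) / self.flow_width) ** 2)
        return (self.flow_base + pulse) * np.exp(log_anomaly)


@dataclass
class ScenarioDelta:
    """Climate-scenario modification of one site's seasonal curves.

    Warming is a baseline offset plus a summer bump (Gaussian in
    day-of-year); the freshet shifts earlier and shrinks, and late-season
    flows scale down, emulating earlier snowmelt and drier summers.
    """

    temp_base: float = 0.0          # year-round warming, degC
    temp_summer_extra: float = 0.0  # additional warming at the summer peak
    temp_peak_doy: float = 200.0
    temp_peak_width: float = 55.0
    flow_peak_shift: float = 0.0    # days (negative = earlier freshet)
    flow_peak_scale: float = 1.0    # multiplier on freshet pulse height
    flow_late_scale: float = 1.0    # multiplier on flows after ~mid-June
    flow_late_ramp_doy: float = 170.0

    def temp_offset(self, doy):
        doy = np.asarray(doy, dtype=float)
        bump = np.exp(-0.5 * ((doy - self.temp_peak_doy) / self.temp_peak_width) ** 2)
        return self.temp_base + self.temp_summer_extra * bump

    def flow_series(self, site: SeasonalSite, doy, log_anomaly=0.0):
        doy = np.asarray(doy, dtype=float)
        pulse = site.flow_peak * self.flow_peak_scale * np.exp(
            -0.5 * ((doy - (site.flow_peak_day + self.flow_peak_shift)) / site.flow_width) ** 2
        )
        base = site.flow_base + pulse
        ramp = 1.0 / (1.0 + np.exp(-(doy - self.flow_late_ramp_doy) / 10.0))
        scale = 1.0 + (self.flow_late_scale - 1.0) * ramp
        return base * scale * np.exp(log_anomaly)


@dataclass
class ArrivalTruth:
    """True arrival-day model per species (metric names, coefficients)."""

    metrics: tuple            # one metric per component
    beta0: tuple
    beta1: tuple
    sigma: tuple
    p_spring: float = 1.0     # weight of first component


@dataclass
class SurvivalTruth:
    """True logistic survival surface for one species/reach.

    Piecewise-linear-in-logit temperature effect with a breakpoint at
    ``t_break`` (slope steeper and negative above), linear flow effect
    (per 100 m3/s), optional log-degree-day and cube-root-catch effects,
    and categorical shifts for juvenile transport, hatchery origin and
    ocean age.  Continuous covariates enter centered so the intercept is
    the logit survival of a baseline fish at typical conditions.
    """

    intercept: float
    t_break: float = 15.0
    slope_t_below: float = 0.02
    slope_t_above: float = -0.2
    flow_coef: float = 0.0       # per 100 m3/s
    flow_center: float = 0.0
    logm_coef: float = 0.0
    logm_center: float = 5.0
    catch_coef: float = 0.0      # per cube-root-catch unit
    catch_center: float = 8.0
    transport_coef: float = 0.0
    hatchery_coef: float = 0.0
    age_coefs: dict = field(default_factory=lambda: {"1": 0.3, "2": 0.0, "3+": -0.15})

    def logit(self, T, F, logM=None, crootC=None, transported=0, hatchery=0, age="2"):
        T = np.asarray(T, dtype=float)
        lo = np.minimum(T - self.t_break, 0.0)
        hi = np.maximum(T - self.t_break, 0.0)
        eta = (
            self.intercept
            + self.slope_t_below * lo
            + self.slope_t_above * hi
            + self.flow_coef * (np.asarray(F, dtype=float) - self.flow_center) / 100.0
        )
        if self.logm_coef and logM is not None:
            eta = eta + self.logm_coef * (np.asarray(logM, dtype=float) - self.logm_center)
        if self.catch_coef and crootC is not None:
            eta = eta + self.catch_coef * (np.asarray(crootC, dtype=float) - self.catch_center)
        eta = eta + self.transport_coef * np.asarray(transported, dtype=float)
        eta = eta + self.hatchery_coef * np.asarray(hatchery, dtype=float)
        age_arr = np.atleast_1d(np.asarray(age, dtype=object))
        eta = eta + np.array([self.age_coefs[str(a)] for a in age_arr], dtype=float)
        return eta

    def prob(self, **kw):
        from scipy.special import expit

        return expit(self.logit(**kw))


@dataclass
class GeneratorConfig:
    """Defaults define the emulated study conditions; see docs/methods.md."""

    years: int = 12
    start_year: int = 2004
    sites: dict = None
    scenario_deltas: dict = None   # scenario -> site -> ScenarioDelta
    temp_year_sd: float = 0.8      # interannual temperature anomaly SD, degC
    flow_year_sd: float = 0.18     # interannual log-flow anomaly SD
    extreme_year_offset: int = 3   # years before the end for the 2015-like year
    transported: dict = None       # species -> proportion
    hatchery: dict = None
    age_probs: dict = None         # species -> {"1": p, "2": p, "3+": p}
    p_spring: float = 0.4
    arrival: dict = None           # species -> ArrivalTruth
    survival: dict = None          # (species, reach) -> SurvivalTruth
    catch_peak: float = 1200.0     # weekly catch at the seasonal peak
    catch_year_sd: float = 0.4     # interannual log-catch SD

    @property
    def year_list(self):
        return list(range(self.start_year, self.start_year + self.years))

    @property
    def extreme_year(self) -> int:
        return self.start_year + self.years - 1 - self.extreme_year_offset


def default_config() -> GeneratorConfig:
    """The default study conditions.

    Cohort composition: 33% of Chinook and 38% of sockeye transported as
    juveniles; 74% / 99% hatchery; ocean-age-2 proportions 0.66 / 0.89.
    Arrival truths use the best-model coefficients of the retrospective
    fits: sockeye mean arrival 1.36 d earlier per degC April temperature;
    spring Chinook 3.06 d earlier per degC; summer Chinook 0.02 d later per
    1000 m3/s April flow.  Survival surfaces decline above 15 degC with a
    negative freshet-flow effect for Chinook in the Columbia and Salmon
    reaches and a strongly positive flow effect for sockeye in the Salmon
    reach; intercepts are calibrated so observed survival reproduces the
    reported stylized facts (sockeye Columbia transported vs in-river
    0.30 vs 0.59).
    """
    sites = {
        "BON": SeasonalSite(12.5, 8.5, flow_base=2500, flow_peak=5000,
                            flow_peak_day=150, flow_width=35),
        "MCN": SeasonalSite(12.8, 8.8, flow_base=2300, flow_peak=4700,
                            flow_peak_day=149, flow_width=34),
        "ICH": SeasonalSite(12.5, 9.2, flow_base=800, flow_peak=2200,
                            flow_peak_day=145, flow_width=30),
        "LGR": SeasonalSite(12.2, 9.0, flow_base=850, flow_peak=2300,
                            flow_peak_day=145, flow_width=30),
        "ANATONE": SeasonalSite(11.8, 10.0, flow_base=800, flow_peak=2100,
                                flow_peak_day=143, flow_width=28),
        "WHITEBIRD": SeasonalSite(11.5, 9.5, flow_base=150, flow_peak=1300,
                                  flow_peak_day=140, flow_width=25),
    }
    # Warming grows moving upstream (roughly +1.3-1.7 degC at Bonneville
    # rising to +2.6-3.4 degC in the Salmon reach at the summer peak); the
    # dry scenario shrinks the freshet, the wet scenario raises it but both
    # lose late-season flow.
    def deltas(scale_t, peak_scale, late_scale, shift):
        return {
            "BON": ScenarioDelta(0.9 * scale_t, 0.7 * scale_t, flow_peak_shift=shift,
                                 flow_peak_scale=peak_scale, flow_late_scale=late_scale),
            "MCN": ScenarioDelta(1.0 * scale_t, 0.9 * scale_t, flow_peak_shift=shift,
                                 flow_peak_scale=peak_scale, flow_late_scale=late_scale),
            "ICH": ScenarioDelta(1.4 * scale_t, 1.2 * scale_t, flow_peak_shift=shift,
                                 flow_peak_scale=peak_scale, flow_late_scale=late_scale),
            "LGR": ScenarioDelta(1.4 * scale_t, 1.2 * scale_t, flow_peak_shift=shift,
                                 flow_peak_scale=peak_scale, flow_late_scale=late_scale),
            "ANATONE": ScenarioDelta(1.7 * scale_t, 1.5 * scale_t, flow_peak_shift=shift,
                                     flow_peak_scale=peak_scale, flow_late_scale=late_scale),
            "WHITEBIRD": ScenarioDelta(1.7 * scale_t, 1.5 * scale_t, flow_peak_shift=shift,
                                       flow_peak_scale=peak_scale,
                                       flow_late_scale=0.8 * late_scale),
        }

    scenario_deltas = {
        "historical": {s: ScenarioDelta() for s in SITES},
        "dry": deltas(scale_t=0.95, peak_scale=0.75, late_scale=0.72, shift=-10.0),
        "wet": deltas(scale_t=1.05, peak_scale=1.10, late_scale=0.80, shift=-12.0),
    }
    arrival = {
        "sockeye": ArrivalTruth(("temp_Apr",), (195.0,), (-1.36,), (6.0,), 1.0),
        "chinook": ArrivalTruth(
            ("temp_Apr", "flow_Apr"), (165.2, 158.9), (-3.06, 0.02), (8.0, 10.0), 0.4
        ),
    }
    survival = {
        ("chinook", "Columbia"): SurvivalTruth(
            intercept=2.75, slope_t_above=-0.25, flow_coef=-0.02, flow_center=5500,
            catch_coef=-0.06, catch_center=8.0, transport_coef=-0.2,
            hatchery_coef=-0.35,
        ),
        ("chinook", "Snake"): SurvivalTruth(
            intercept=4.02, slope_t_above=-0.2, flow_coef=-0.01, flow_center=1500,
            logm_coef=-0.4, logm_center=4.6, transport_coef=-0.1,
            hatchery_coef=-0.1,
        ),
        ("chinook", "Salmon"): SurvivalTruth(
            intercept=2.78, slope_t_above=-0.15, flow_coef=-0.05, flow_center=500,
            logm_coef=-0.35, logm_center=5.0, transport_coef=-0.05,
            hatchery_coef=-0.1,
        ),
        ("sockeye", "Columbia"): SurvivalTruth(
            intercept=1.77, slope_t_above=-0.22, slope_t_below=0.03,
            catch_coef=-0.12, catch_center=8.0, transport_coef=-1.25,
            age_coefs={"1": 0.3, "2": 0.0, "3+": -0.2},
        ),
        ("sockeye", "Snake"): SurvivalTruth(
            intercept=3.18, slope_t_above=-0.25, flow_coef=0.0, flow_center=900,
            logm_coef=-0.5, logm_center=4.9, transport_coef=-0.35,
        ),
        ("sockeye", "Salmon"): SurvivalTruth(
            intercept=2.34, slope_t_above=-0.3, flow_coef=0.35, flow_center=300,
            logm_coef=-0.6, logm_center=5.3, transport_coef=-0.3,
        ),
    }
    return GeneratorConfig(
        sites=sites,
        scenario_deltas=scenario_deltas,
        transported={"chinook": 0.33, "sockeye": 0.38},
        hatchery={"chinook": 0.74, "sockeye": 0.99},
        age_probs={
            "chinook": {"1": 0.17, "2": 0.66, "3+": 0.17},
            "sockeye": {"1": 0.06, "2": 0.89, "3+": 0.05},
        },
        arrival=arrival,
        survival=survival,
    )


# ---------------------------------------------------------------------------
# Environmental scenarios
# ---------------------------------------------------------------------------

def _make_env(config, scenario, years, rng, extreme_year=None) -> dict:
    """Daily EnvSeries per site for one scenario over ``years`` (list)."""
    out = {}
    # Shared interannual anomalies so sites co-vary (basin-wide weather).
    t_anom = {y: rng.normal(0.0, config.temp_year_sd) for y in years}
    f_anom = {y: rng.normal(0.0, config.flow_year_sd) for y in years}
    if extreme_year is not None and extreme_year in t_anom:
        t_anom[extreme_year] = 2.0 * config.temp_year_sd
        f_anom[extreme_year] = -2.0 * config.flow_year_sd
    for site in SITES:
        ss = config.sites[site]
        delta = config.scenario_deltas[scenario][site]
        frames = []
        for y in years:
            idx = pd.date_range(date(y, 1, 1), date(y, 12, 31), freq="D")
            doy = idx.dayofyear.to_numpy(dtype=float)
            n = len(idx)
            noise_t = np.empty(n)
            noise_t[0] = rng.normal(0, ss.temp_noise_sd)
            for i in range(1, n):  # AR(1) daily weather
                noise_t[i] = 0.7 * noise_t[i - 1] + rng.normal(0, ss.temp_noise_sd)
            temp = ss.temperature(doy, anomaly=t_anom[y]) + delta.temp_offset(doy) + noise_t
            flow = delta.flow_series(ss, doy, log_anomaly=f_anom[y])
            flow = flow * np.exp(rng.normal(0, ss.flow_noise_sd, size=n))
            frames.append(pd.DataFrame(
                {"temperature": temp, "flow": np.maximum(flow, 1.0)}, index=idx
            ))
        data = pd.concat(frames)
        out[site] = EnvSeries(site=site, scenario=scenario, data=data)
    return out


def make_observed_env(config: GeneratorConfig, rng) -> dict:
    """The retrospective ("observed") environment, including one flagged
    2015-like extreme year (+2 SD run-window temperature, -2 SD flow)."""
    return _make_env(config, "historical", config.year_list, rng,
                     extreme_year=config.extreme_year)


def make_env_scenarios(config: GeneratorConfig, rng, years=None) -> dict:
    """Historical/dry/wet scenario environments: scenario -> site -> EnvSeries."""
    if years is None:
        years = config.year_list
    return {
        scen: _make_env(config, scen, list(years), rng)
        for scen in ("historical", "dry", "wet")
    }


def make_catch_series(config: GeneratorConfig, rng, years=None) -> CatchSeries:
    """Weekly Zone 6 catch: seasonal bump over the run, lognormal years."""
    if years is None:
        years = config.year_list
    year_scale = {y: np.exp(rng.normal(0.0, config.catch_year_sd)) for y in years}
    start = pd.Timestamp(date(min(years), 1, 1))
    start = start + timedelta(days=(7 - start.weekday()) % 7)  # first Monday
    end = pd.Timestamp(date(max(years), 12, 31))
    weeks = pd.date_range(start, end, freq="7D")
    values = []
    for wk in weeks:
        seasonal = np.exp(-0.5 * ((wk.dayofyear - 180) / 35.0) ** 2)
        lam = config.catch_peak * year_scale.get(wk.year, 1.0) * seasonal
        values.append(float(rng.poisson(lam)))
    return CatchSeries(pd.Series(values, index=weeks))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_SPRING_POPS = ("Grande Ronde", "Middle Fork Salmon", "Upper Salmon")
_SUMMER_POPS = ("South Fork Salmon", "Imnaha", "Pahsimeroi")


def _sample_arrival(config, species, cov: pd.DataFrame, year, n, rng):
    truth = config.arrival[species]
    k = len(truth.metrics)
    w = np.array([truth.p_spring, 1 - truth.p_spring])[:k]
    w = w / w.sum()
    comp = rng.choice(k, size=n, p=w)
    mu = np.array(
        [truth.beta0[j] + truth.beta1[j] * cov.loc[year, truth.metrics[j]]
         for j in range(k)]
    )
    sigma = np.array(truth.sigma)
    day = rng.normal(mu[comp], sigma[comp])
    return np.clip(np.rint(day).astype(int), 60, 330), comp


def make_cohort(
    config: GeneratorConfig,
    env: dict,
    catch: CatchSeries,
    rng,
    species: str = "sockeye",
    n_fish: int = 2000,
    travel_model: TravelTimeModel | None = None,
):
    """Generate ``n_fish`` tagged adults with reach outcomes and truths.

    Fish are spread evenly over the configured years.  Arrival day comes
    from the true arrival model driven by the generated annual April
    metrics; passage dates from the travel-time truth; per-reach survival
    is Bernoulli from the true logistic surfaces.  Returns
    ``(records, truth)`` where ``truth`` has one row per fish x entered
    reach with the true survival probability and the realized outcome.
    """
    if travel_model is None:
        travel_model = default_travel_model(species)
    cov = annual_covariates(env["BON"])
    years = config.year_list
    per_year = np.full(len(years), n_fish // len(years))
    per_year[: n_fish % len(years)] += 1
    records, truth_rows = [], []
    fish_no = 0
    for y, ny in zip(years, per_year):
        days, comps = _sample_arrival(config, species, cov, y, ny, rng)
        transported = rng.random(ny) < config.transported[species]
        hatchery = rng.random(ny) < config.hatchery[species]
        ages = rng.choice(
            list(config.age_probs[species]), size=ny,
            p=list(config.age_probs[species].values()),
        )
        for i in range(ny):
            fish_no += 1
            fid = f"{species[:2].upper()}{fish_no:06d}"
            bon = date(y, 1, 1) + timedelta(days=int(days[i]) - 1)
            detections, censored = travel_model.simulate_passage(bon, env, rng)
            if species == "chinook":
                run = "spring" if comps[i] == 0 else "summer"
                pops = _SPRING_POPS if run == "spring" else _SUMMER_POPS
                pop = pops[rng.choice(len(pops))]
            else:
                run, pop = None, "Sawtooth"
            age = str(ages[i])
            reach_surv = {r: "not_applicable" for r in REACH_ORDER}
            alive = True
            final_detections = {"BON": bon}
            for reach_name in REACH_ORDER:
                if not alive:
                    break
                rd = REACHES[reach_name]
                if rd.entry_dam not in detections:
                    # censored before reach entry: conservative death
                    if censored:
                        reach_surv[reach_name] = "died"
                    break
                entry_reach_detections = {
                    s: d for s, d in detections.items()
                    if ROUTE.index(s) <= ROUTE.index(rd.entry_dam)
                }
                final_detections.update(entry_reach_detections)
                fish_tmp = FishRecord(
                    fid, species, pop, run, int(age.replace("+", "")),
                    "hatchery" if hatchery[i] else "wild",
                    "transported" if transported[i] else "in_river",
                    y, detections, {},
                )
                try:
                    T, F = reach_conditions(fish_tmp, env, rd)
                except Exception:
                    reach_surv[reach_name] = "died" if censored else "not_applicable"
                    break
                st = config.survival[(species, reach_name)]
                logM = None
                if reach_name in ("Snake", "Salmon"):
                    M = cumulative_temp(fish_tmp, env, reach_name)
                    logM = float(log_degree_days(M))
                crootC = None
                if reach_name == "Columbia":
                    crootC = float(cube_root(align_catch(fish_tmp, catch)))
                p = float(
                    np.ravel(
                        st.prob(
                            T=T, F=F, logM=logM, crootC=crootC,
                            transported=int(transported[i]),
                            hatchery=int(hatchery[i]), age=age,
                        )
                    )[0]
                )
                survived = bool(rng.random() < p)
                # Exit detection exists only if the fish survived and the
                # travel simulation reached the exit.
                if survived and rd.exit_site not in detections:
                    survived = False  # censored en route: conservative death
                reach_surv[reach_name] = "survived" if survived else "died"
                truth_rows.append(
                    {"fish_id": fid, "species": species, "reach": reach_name,
                     "year": y, "p_true": p, "outcome": int(survived),
                     "T": T, "F": F}
                )
                if survived:
                    exit_idx = ROUTE.index(rd.exit_site)
                    final_detections.update(
                        {s: d for s, d in detections.items()
                         if ROUTE.index(s) <= exit_idx}
                    )
                else:
                    alive = False
            rec = FishRecord(
                fish_id=fid,
                species=species,
                population=pop,
                run=run,
                ocean_age=int(age.replace("+", "")) if age != "3+" else 3,
                origin="hatchery" if hatchery[i] else "wild",
                juv_history="transported" if transported[i] else "in_river",
                migration_year=y,
                detections=final_detections,
                reach_survival=reach_surv,
            )
            rec.validate()
            records.append(rec)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def bayes_auc(truth: pd.DataFrame, reach: str | None = None) -> float:
    """AUC of the generator's true probabilities against realized outcomes.

    This is the best achievable (Bayes) discrimination for the generated
    data; a well-specified fitted model's AUC should approach it.
    """
    sub = truth if reach is None else truth[truth["reach"] == reach]
    return _auc(sub["p_true"].to_numpy(), sub["outcome"].to_numpy())
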