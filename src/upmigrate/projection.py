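"""Prospective Monte-Carlo survival projection under climate scenarios.

The four-step simulation: (1) arrival days at Bonneville are drawn from the
fitted arrival model using annual metrics of the scenario environment;
(2) the travel-time model moves each fish up the route, aligning
reach-specific conditions; (3) reach survival probabilities come from the
fitted survival models with the year random effect set to zero, and reach
outcomes are Bernoulli; (4) the whole pipeline is looped over years,
scenarios, and parameter draws, with one multivariate-normal draw per model
per loop (from the retrospective coefficient covariances) so the spread
across loops carries parameter uncertainty.  Catch, juvenile transport rate
and hatchery proportion are re-drawn per simulated year by bootstrap over
the observed annual values.

Cumulative survival is the product of the three reach indicators per fish.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .arrival import ArrivalTimingResults, annual_covariates
from .covariates import cube_root, log_degree_days
from .io import REACHES, REACH_ORDER, CatchSeries, EnvSeries, ValidationError
from .travel import LEG_ORDER, TravelTimeModel, default_travel_model

__all__ = [
    "SimulationConfig",
    "ScenarioRun",
    "total_fish",
    "rng_for",
    "draw_parameter_set",
    "simulate_cohort",
    "run_projection",
    "summarize_runs",
    "observed_annual_rates",
]


def observed_annual_rates(records, catch: CatchSeries) -> pd.DataFrame:
    """Empirical annual anthropogenic covariates from an observation cohort.

    One row per migration year: juvenile transport rate, hatchery
    proportion, ocean-age composition, and the mean weekly catch over the
    weeks in which that year's fish passed Bonneville.  The projection
    bootstraps rows of this table to emulate interannual variability.
    """
    rows = {}
    for r in records:
        y = r.migration_year
        d = rows.setdefault(
            y, {"n": 0, "transported": 0, "hatchery": 0,
                "age1": 0, "age2": 0, "age3": 0, "catch": []}
        )
        d["n"] += 1
        d["transported"] += r.juv_history == "transported"
        d["hatchery"] += r.origin == "hatchery"
        key = "age1" if r.ocean_age == 1 else ("age2" if r.ocean_age == 2 else "age3")
        d[key] += 1
        bon = r.detections.get("BON")
        if bon is not None:
            try:
                d["catch"].append(catch.catch_in_week_of(bon))
            except ValidationError:
                pass
    out = []
    for y, d in sorted(rows.items()):
        n = d["n"]
        out.append(
            {"year": y, "transport_rate": d["transported"] / n,
             "hatchery_rate": d["hatchery"] / n,
             "age1": d["age1"] / n, "age2": d["age2"] / n, "age3": d["age3"] / n,
             "weekly_catch": float(np.mean(d["catch"])) if d["catch"] else 0.0}
        )
    return pd.DataFrame(out)


@dataclass
class SimulationConfig:
    """Projection design (defaults are the full published design)."""

    n_fish_per_year: int = 100
    n_loops: int = 200
    n_years: int = 70
    scenarios: tuple = ("historical", "dry", "wet")
    species: tuple = ("chinook", "sockeye")
    master_seed: int = 0

    def __post_init__(self):
        for name in ("n_fish_per_year", "n_loops", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def total_fish(config: SimulationConfig) -> int:
    """Closed-form size of the projection: fish x years x scenarios x loops x species."""
    return (
        config.n_fish_per_year
        * config.n_years
        * len(config.scenarios)
        * config.n_loops
        * len(config.species)
    )


def rng_for(master_seed: int, *keys) -> np.random.Generator:
    """Hierarchically seeded generator: any cell independently reproducible."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, keys)]))


# ---------------------------------------------------------------------------
# Parameter uncertainty
# ---------------------------------------------------------------------------

def _draw_arrival(results: ArrivalTimingResults, rng) -> ArrivalTimingResults:
    """One MVN draw of the arrival parameters (natural scale)."""
    eta = results.params.to_numpy().copy()
    cov = np.array(results.cov, dtype=float)
    free = np.isfinite(np.diag(cov))
    cov = np.where(np.isfinite(cov), cov, 0.0)
    sub = cov[np.ix_(free, free)]
    w, V = np.linalg.eigh((sub + sub.T) / 2.0)
    sub = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
    draw = eta.copy()
    draw[free] = rng.multivariate_normal(eta[free], sub, method="eigh")
    k = results.n_components
    b0, b1 = draw[0:k], draw[k:2 * k]
    sigma = np.clip(draw[2 * k:3 * k], 0.5, None)
    theta = np.concatenate([b0, b1, np.log(sigma)])
    if k == 2:
        p = float(np.clip(draw[-1], 1e-4, 1 - 1e-4))
        theta = np.concatenate([theta, [np.log(p / (1 - p))]])
    return ArrivalTimingResults(
        model=results.model, theta=theta, loglik=np.nan, cov=results.cov,
        param_names=results.param_names,
    )


def draw_parameter_set(arrival_results: dict, survival_results: dict, rng) -> dict:
    """One parameter draw per model (arrival per species, survival per reach).

    ``arrival_results`` maps species to fitted arrival results;
    ``survival_results`` maps (species, reach) to fitted survival results.
    A zero covariance returns the point estimates exactly.
    """
    return {
        "arrival": {sp: _draw_arrival(res, rng) for sp, res in arrival_results.items()},
        "survival_beta": {
            key: res.draw_beta(rng) for key, res in survival_results.items()
        },
    }


# ---------------------------------------------------------------------------
# One cohort (year x scenario x species)
# ---------------------------------------------------------------------------

def _fish_reach_rows(species, bon_dates, env, weekly_catch, travel_model, rng):
    """Travel each fish up the route; return per-fish covariates per reach.

    Returns a dict reach -> DataFrame (one row per fish: T, F, logM, crootC)
    plus a per-fish censored flag.  Censored fish (travel truncated or
    beyond env coverage) get NaN covariates and count as deaths.
    """
    n = len(bon_dates)
    rows = {r: [] for r in REACH_ORDER}
    censored = np.zeros(n, dtype=bool)
    for i, bon in enumerate(bon_dates):
        detections, cens = travel_model.simulate_passage(bon, env, rng)
        fish_rows = {}
        M_legs = {}
        try:
            for reach_name in REACH_ORDER:
                rd = REACHES[reach_name]
                entry = detections.get(rd.entry_dam)
                if entry is None:
                    raise ValidationError("censored before reach entry")
                w = rd.window(species)
                T = env[rd.temp_site].window_mean("temperature", entry, w)
                F = env[rd.flow_site].window_mean("flow", entry, w)
                row = {"T": T, "F": F, "logM": np.nan, "crootC": np.nan}
                if reach_name in ("Snake", "Salmon"):
                    legs = [("BON", "MCN"), ("MCN", "ICH")]
                    if reach_name == "Salmon":
                        legs.append(("ICH", "LGR"))
                    M = 0.0
                    for a, b in legs:
                        D = (detections[b] - detections[a]).days
                        Ta = env[a].value_on("temperature", detections[a])
                        Tb = env[b].value_on("temperature", detections[b])
                        M += D * (Ta + Tb) / 2.0
                    row["logM"] = float(log_degree_days(M))
                if reach_name == "Columbia":
                    row["crootC"] = float(cube_root(weekly_catch))
                fish_rows[reach_name] = row
        except (ValidationError, KeyError):
            censored[i] = True
            fish_rows = {
                r: {"T": np.nan, "F": np.nan, "logM": np.nan, "crootC": np.nan}
                for r in REACH_ORDER
            }
        for r in REACH_ORDER:
            rows[r].append(fish_rows[r])
    return {r: pd.DataFrame(v) for r, v in rows.items()}, censored


def simulate_cohort(
    species: str,
    year: int,
    env: dict,
    arrival_draw: ArrivalTimingResults,
    survival_results: dict,
    survival_beta: dict,
    annual_rates: pd.DataFrame,
    config: SimulationConfig,
    rng,
    travel_model: TravelTimeModel | None = None,
    arrival_shift_days: float = 0.0,
) -> pd.DataFrame:
    """Simulate one year's cohort for one species under one scenario.

    ``env`` maps site to that scenario's EnvSeries (covering ``year``);
    ``annual_rates`` holds the observed annual covariate draws (columns
    ``transport_rate``, ``hatchery_rate``, ``weekly_catch``) to bootstrap
    from.  Returns a per-fish frame with reach survival indicators,
    cumulative survival, and run component labels.
    """
    if travel_model is None:
        travel_model = default_travel_model(species)
    n = config.n_fish_per_year
    cov = annual_covariates(env["BON"])
    if year not in cov.index:
        raise ValidationError(f"no annual covariates for year {year}")
    arr = arrival_draw.simulate(cov, n, rng, years=[year])
    days = arr["day"].to_numpy() - arrival_shift_days
    days = np.clip(np.rint(days).astype(int), 32, 330)
    bon_dates = [date(year, 1, 1) + timedelta(days=int(d) - 1) for d in days]
    # Interannual anthropogenic covariates: bootstrap one observed year.
    boot = annual_rates.iloc[rng.integers(len(annual_rates))]
    transported = rng.random(n) < float(boot["transport_rate"])
    hatchery = rng.random(n) < float(boot["hatchery_rate"])
    weekly_catch = float(boot["weekly_catch"])
    age_levels = ["1", "2", "3+"]
    age_p = np.array([boot.get("age1", 0.15), boot.get("age2", 0.7),
                      boot.get("age3", 0.15)], dtype=float)
    ages = np.array(age_levels)[rng.choice(3, size=n, p=age_p / age_p.sum())]

    reach_rows, censored = _fish_reach_rows(
        species, bon_dates, env, weekly_catch, travel_model, rng
    )
    out = pd.DataFrame(
        {
            "species": species,
            "year": year,
            "component": arr["component"].to_numpy(),
            "day": days,
            "censored": censored,
        }
    )
    cumulative = np.ones(n)
    for reach_name in REACH_ORDER:
        key = (species, reach_name)
        res = survival_results[key]
        beta = survival_beta.get(key)
        df = reach_rows[reach_name].copy()
        df["population"] = res.baseline_population
        df["A"] = ages
        df["J"] = np.where(transported, "transported", "in_river")
        df["H"] = np.where(hatchery, "hatchery", "wild")
        ok = ~df["T"].isna()
        p = np.zeros(n)
        if ok.any():
            p[ok.to_numpy()] = res.predict(df[ok], year_effect=0.0, beta=beta)
        survived = (rng.random(n) < p) & ~censored
        out[f"p_{reach_name}"] = p
        out[f"surv_{reach_name}"] = survived.astype(int)
        cumulative *= survived
    out["cumulative"] = cumulative.astype(int)
    return out


# ---------------------------------------------------------------------------
# Full projection
# ---------------------------------------------------------------------------

@dataclass
class ScenarioRun:
    """Projection output: annual summaries per loop plus design metadata."""

    annual: pd.DataFrame          # loop x scenario x year x species (x component)
    summary: pd.DataFrame         # Table-4-style mean (SD) and % change
    config: SimulationConfig

    def percent_change(self) -> pd.DataFrame:
        return self.summary[self.summary["scenario"] != "historical"][
            ["scenario", "species", "component", "reach", "pct_change"]
        ]

    def plot_survival(self, species: str, component: str = "aggregate", ax=None):
        """Boxplots of annual survival by reach and scenario."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.annual[
            (self.annual.species == species)
            & (self.annual.component == component)
        ]
        reaches = list(REACH_ORDER) + ["cumulative"]
        scenarios = list(self.config.scenarios)
        data, labels = [], []
        for reach in reaches:
            col = f"surv_{reach}" if reach != "cumulative" else "cumulative"
            for scen in scenarios:
                data.append(sub[sub.scenario == scen][col].to_numpy())
                labels.append(f"{reach}\n{scen}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("annual survival")
        ax.set_title(f"{species} ({component})")
        ax.tick_params(axis="x", labelsize=7)
        return ax


def _annual_summary(fish: pd.DataFrame) -> list:
    """Annual survival proportions per reach/cumulative, by run component."""
    rows = []
    groups = [("aggregate", fish)]
    for comp, sub in fish.groupby("component"):
        if comp != "single":
            groups.append((comp, sub))
    for comp, sub in groups:
        if sub.empty:
            continue
        row = {"component": comp, "n": len(sub)}
        for reach in REACH_ORDER:
            row[f"surv_{reach}"] = sub[f"surv_{reach}"].mean()
        row["cumulative"] = sub["cumulative"].mean()
        rows.append(row)
    return rows


def run_projection(
    arrival_results: dict,
    survival_results: dict,
    env_scenarios: dict,
    annual_rates: dict,
    config: SimulationConfig,
    travel_models: dict | None = None,
    arrival_shift_days: float = 0.0,
    seed_offset: int = 0,
) -> ScenarioRun:
    """Loop the cohort simulation over loops x scenarios x years x species.

    ``env_scenarios`` maps scenario -> site -> EnvSeries (all years);
    ``annual_rates`` maps species -> DataFrame of observed annual rates.
    ``seed_offset`` offsets the hierarchical seed keys, letting sensitivity
    grids reuse the base seeds (common random numbers) or not.
    """
    if travel_models is None:
        travel_models = {sp: default_travel_model(sp) for sp in config.species}
    records = []
    scen_list = list(config.scenarios)
    for loop in range(config.n_loops):
        draw_rng = rng_for(config.master_seed, 1, loop + seed_offset)
        draw = draw_parameter_set(arrival_results, survival_results, draw_rng)
        for s_idx, scenario in enumerate(scen_list):
            env = env_scenarios[scenario]
            years = sorted({d.year for d in env["BON"].dates})[: config.n_years]
            for y_idx, year in enumerate(years):
                for sp_idx, species in enumerate(config.species):
                    rng = rng_for(
                        config.master_seed, 2, loop + seed_offset, s_idx, y_idx, sp_idx
                    )
                    fish = simulate_cohort(
                        species, year, env,
                        draw["arrival"][species],
                        survival_results, draw["survival_beta"],
                        annual_rates[species], config, rng,
                        travel_model=travel_models[species],
                        arrival_shift_days=arrival_shift_days,
                    )
                    for row in _annual_summary(fish):
                        row.update(
                            {"loop": loop, "scenario": scenario, "year": year,
                             "species": species}
                        )
                        records.append(row)
    annual = pd.DataFrame(records)
    summary = summarize_runs(annual)
    return ScenarioRun(annual=annual, summary=summary, config=config)


def summarize_runs(annual: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) survival by scenario/species/component/reach and the
    percent change of each future scenario relative to historical."""
    value_cols = [f"surv_{r}" for r in REACH_ORDER] + ["cumulative"]
    long = annual.melt(
        id_vars=["scenario", "species", "component", "loop", "year"],
        value_vars=value_cols, var_name="reach", value_name="survival",
    )
    long["reach"] = long["reach"].str.replace("surv_", "", regex=False)
    g = long.groupby(["scenario", "species", "component", "reach"])["survival"]
    summary = g.agg(["mean", "std"]).reset_index()
    hist = summary[summary["scenario"] == "historical"].set_index(
        ["species", "component", "reach"]
    )["mean"]

    def pct(row):
        if row["scenario"] == "historical":
            return np.nan
        base = hist.get((row["species"], row["component"], row["reach"]), np.nan)
        if not np.isfinite(base) or base == 0:
            return np.nan
        return 100.0 * (row["mean"] - base) / base

    summary["pct_change"] = summary.apply(pct, axis=1)
    return summary
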