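"""Declarative pipeline configuration, validation, and the run-all driver.

A single YAML config governs the five-stage pipeline: (1) synthetic data
generation, (2) retrospective fits (arrival timing, reach survival),
(3) prospective projection, (4) sensitivity grids, (5) the 2015-reference
exceedance comparison.  Every stage writes its outputs under the configured
directory together with a provenance JSON (config hash, master seed,
package version, record counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrival import annual_covariates, select_arrival_model
from .covariates import build_design_table
from .io import REACH_ORDER, write_catch_series, write_env_series, write_fish_table
from .projection import (
    SimulationConfig,
    observed_annual_rates,
    run_projection,
)
from .scenarios import annual_window_means, compare_to_reference, run_window_from_entries
from .sensitivity import SensitivitySpec, run_sensitivity_grid
from .survival import dredge_select, prefilter_smooths, ReachSurvivalModel
from .synthetic import (
    default_config,
    make_catch_series,
    make_cohort,
    make_env_scenarios,
    make_observed_env,
)
from .travel import default_travel_model

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("synthetic", "arrival", "survival", "projection", "sensitivity", "compare")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Pipeline-wide settings; module defaults are used where not given."""

    out_dir: str = "pipeline_out"
    master_seed: int = 0
    log_level: str = "INFO"
    # synthetic stage
    n_chinook: int = 3000
    n_sockeye: int = 1500
    generator_years: int = 12
    # arrival stage
    arrival_candidates: tuple = ("temp_Apr", "flow_Apr")
    arrival_restarts: int = 4
    # survival stage
    dredge: bool = False
    knots: dict = field(default_factory=dict)
    # projection stage
    n_fish_per_year: int = 50
    n_loops: int = 5
    n_years: int = 12
    scenarios: tuple = ("historical", "dry", "wet")
    species: tuple = ("chinook", "sockeye")
    # sensitivity stage
    sensitivity_axes: tuple = ("temp",)
    arrival_shifts_days: tuple = (3, 6, 9, 12, 14)
    temp_deltas_C: tuple = (-0.8, -0.4, 0.4, 0.8, 1.2, 1.6, 2.0)
    flow_factors: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.2, 1.4)
    flow_floor: float = 10.0
    # comparison stage
    reference_year: int | None = None  # default: the generator's extreme year

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("arrival_candidates", "scenarios", "species",
                    "sensitivity_axes", "arrival_shifts_days",
                    "temp_deltas_C", "flow_factors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def validate_config(config: PipelineConfig) -> list:
    """Constraint check; returns a list of violation strings (empty = OK)."""
    problems = []
    for name in ("n_chinook", "n_sockeye", "generator_years",
                 "n_fish_per_year", "n_loops", "n_years"):
        if getattr(config, name) < 1:
            problems.append(f"{name} must be >= 1 (got {getattr(config, name)})")
    if config.flow_floor <= 0:
        problems.append(f"flow_floor must be positive (got {config.flow_floor})")
    for term, k in (config.knots or {}).items():
        if k not in (3, 4):
            problems.append(f"knots[{term}] must be 3 or 4 (got {k})")
    for sp in config.species:
        if sp not in ("chinook", "sockeye"):
            problems.append(f"unknown species {sp!r}")
    for sc in config.scenarios:
        if sc not in ("historical", "dry", "wet"):
            problems.append(f"unknown scenario {sc!r}")
    for ax in config.sensitivity_axes:
        if ax not in ("arrival", "temp", "flow"):
            problems.append(f"unknown sensitivity axis {ax!r}")
    if any(d < 0 for d in config.arrival_shifts_days):
        problems.append("arrival shifts are days earlier and must be >= 0")
    return problems


def _provenance(config, stage, seed, extra=None) -> dict:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    out = {
        "stage": stage,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": seed,
        "package_version": __version__,
    }
    if extra:
        out.update(extra)
    return out


def _write_provenance(path: Path, prov: dict) -> None:
    path.write_text(json.dumps(prov, indent=2, default=str))


_GLOBAL_TERMS = {
    # (species, reach) -> (smooth terms, factor terms) for the global model
    ("chinook", "Columbia"): (("T", "F", "C"), ("H", "J", "A", "P")),
    ("chinook", "Snake"): (("T", "F", "M"), ("H", "J", "A", "P")),
    ("chinook", "Salmon"): (("T", "F", "M"), ("H", "J", "A")),
    ("sockeye", "Columbia"): (("T", "F", "C"), ("J", "A")),
    ("sockeye", "Snake"): (("T", "F", "M"), ("J", "A")),
    ("sockeye", "Salmon"): (("T", "F", "M"), ("J", "A")),
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order on synthetic data; returns the output dir.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are kept.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed
    gen_cfg = default_config()
    gen_cfg.years = config.generator_years
    timings = {}

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.time() - self_inner.t0, 2)
                if exc is not None:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                    raise PipelineError(name, str(exc)) from exc
                logger.info("stage %s: done in %.1fs", name, timings[name])
                return False

        return _Ctx()

    # ---- stage 1: synthetic data ----------------------------------------
    with stage("synthetic"):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
        env_obs = make_observed_env(gen_cfg, rng)
        catch = make_catch_series(gen_cfg, rng)
        cohorts, truths = {}, {}
        for sp, n in (("chinook", config.n_chinook), ("sockeye", config.n_sockeye)):
            if sp in config.species:
                cohorts[sp], truths[sp] = make_cohort(
                    gen_cfg, env_obs, catch, rng, species=sp, n_fish=n
                )
        syn_dir = out / "synthetic"
        syn_dir.mkdir(exist_ok=True)
        for sp, recs in cohorts.items():
            write_fish_table(recs, syn_dir / f"fish_{sp}.csv")
        for site, e in env_obs.items():
            write_env_series(e, syn_dir / f"env_observed_{site}.csv")
        write_catch_series(catch, syn_dir / "catch.csv")
        _write_provenance(
            syn_dir / "provenance.json",
            _provenance(config, "synthetic", seed,
                        {"n_fish": {sp: len(r) for sp, r in cohorts.items()}}),
        )

    # ---- stage 2a: arrival fits ------------------------------------------
    with stage("arrival"):
        cov = annual_covariates(env_obs["BON"])
        arrival_results = {}
        arr_dir = out / "arrival"
        arr_dir.mkdir(exist_ok=True)
        for sp, recs in cohorts.items():
            days = np.array(
                [r.detections["BON"].timetuple().tm_yday for r in recs]
            )
            years = np.array([r.migration_year for r in recs])
            k = 2 if sp == "chinook" else 1
            res, table = select_arrival_model(
                days, years, cov, n_components=k,
                candidates=list(config.arrival_candidates),
                n_restarts=config.arrival_restarts, seed=seed,
            )
            arrival_results[sp] = res
            (arr_dir / f"arrival_{sp}.json").write_text(
                json.dumps(res.to_dict(), indent=1)
            )
            table.assign(spec=table["spec"].astype(str)).to_csv(
                arr_dir / f"ranking_{sp}.csv", index=False
            )
        _write_provenance(arr_dir / "provenance.json",
                          _provenance(config, "arrival", seed))

    # ---- stage 2b: survival fits -----------------------------------------
    with stage("survival"):
        surv_dir = out / "survival"
        surv_dir.mkdir(exist_ok=True)
        survival_results = {}
        for sp, recs in cohorts.items():
            for reach in REACH_ORDER:
                design = build_design_table(recs, env_obs, catch, reach, species=sp)
                design.to_csv(surv_dir / f"design_{sp}_{reach}.csv", index=False)
                smooths, factors = _GLOBAL_TERMS[(sp, reach)]
                smooths, dropped = prefilter_smooths(design, smooths)
                if dropped:
                    logger.warning(
                        "%s/%s: dropped collinear smooth terms %s (|r| >= 0.7)",
                        sp, reach, dropped,
                    )
                if config.dredge:
                    res, table = dredge_select(
                        design, smooths, factors, species=sp, reach=reach,
                        knots=config.knots or None,
                    )
                    table.to_csv(
                        surv_dir / f"ranking_{sp}_{reach}.csv", index=False
                    )
                else:
                    res = ReachSurvivalModel(
                        design, smooths, factors, species=sp, reach=reach,
                        knots=config.knots or None,
                    ).fit()
                survival_results[(sp, reach)] = res
                (surv_dir / f"survival_{sp}_{reach}.json").write_text(
                    json.dumps(res.predictor().to_dict())
                )
        _write_provenance(surv_dir / "provenance.json",
                          _provenance(config, "survival", seed))

    # ---- stage 3: projection ---------------------------------------------
    with stage("projection"):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 30]))
        env_scen = make_env_scenarios(
            gen_cfg, rng,
            years=range(gen_cfg.start_year, gen_cfg.start_year + config.n_years),
        )
        rates = {
            sp: observed_annual_rates(recs, catch) for sp, recs in cohorts.items()
        }
        sim_cfg = SimulationConfig(
            n_fish_per_year=config.n_fish_per_year, n_loops=config.n_loops,
            n_years=config.n_years, scenarios=config.scenarios,
            species=tuple(cohorts), master_seed=seed,
        )
        run = run_projection(arrival_results, survival_results, env_scen,
                             rates, sim_cfg)
        proj_dir = out / "projection"
        proj_dir.mkdir(exist_ok=True)
        run.annual.to_csv(proj_dir / "annual.csv", index=False)
        run.summary.to_csv(proj_dir / "summary.csv", index=False)
        _write_provenance(
            proj_dir / "provenance.json",
            _provenance(config, "projection", seed,
                        {"total_fish_design": int(
                            sim_cfg.n_fish_per_year * sim_cfg.n_years
                            * len(sim_cfg.scenarios) * sim_cfg.n_loops
                            * len(sim_cfg.species))}),
        )

    # ---- stage 4: sensitivity --------------------------------------------
    with stage("sensitivity"):
        spec = SensitivitySpec(
            arrival_shifts_days=config.arrival_shifts_days,
            temp_deltas_C=config.temp_deltas_C,
            flow_factors=config.flow_factors,
            flow_floor=config.flow_floor,
        )
        grid = run_sensitivity_grid(
            spec, arrival_results, survival_results, env_scen, rates, sim_cfg,
            axes=config.sensitivity_axes,
        )
        sens_dir = out / "sensitivity"
        sens_dir.mkdir(exist_ok=True)
        grid.to_csv(sens_dir / "grid.csv", index=False)
        _write_provenance(sens_dir / "provenance.json",
                          _provenance(config, "sensitivity", seed))

    # ---- stage 5: 2015 comparison ----------------------------------------
    with stage("compare"):
        ref_year = config.reference_year or gen_cfg.extreme_year
        windows, references = {}, {}
        from .io import REACHES

        for sp, recs in cohorts.items():
            for reach in REACH_ORDER:
                rd = REACHES[reach]
                entries = [
                    r.detections[rd.entry_dam] for r in recs
                    if rd.entry_dam in r.detections
                ]
                if len(entries) < 20:
                    continue
                win = run_window_from_entries(sp, reach, entries)
                site = rd.temp_site
                windows[(sp, reach, site)] = win
                means = annual_window_means(env_obs[site], win)
                if ref_year in means.index:
                    references[(sp, reach, site, "temp")] = float(
                        means.loc[ref_year, "temp"]
                    )
                    references[(sp, reach, site, "flow")] = float(
                        means.loc[ref_year, "flow"]
                    )
        table = compare_to_reference(env_scen, windows, references)
        cmp_dir = out / "compare"
        cmp_dir.mkdir(exist_ok=True)
        table.to_csv(cmp_dir / "exceedance.csv", index=False)
        _write_provenance(
            cmp_dir / "provenance.json",
            _provenance(config, "compare", seed, {"reference_year": ref_year}),
        )

    _write_provenance(out / "provenance.json",
                      _provenance(config, "run-all", seed, {"timings_s": timings}))
    return out
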