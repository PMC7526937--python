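"""Per-fish design-table construction for the reach survival models.

For each fish and reach this module assembles the covariates of the survival
model: reach-entry temperature T (degC) and flow F (m3/s), cumulative
thermal load M (degree-days accumulated from Bonneville to reach entry),
weekly fishery catch C aligned to the Bonneville passage week, and the
categorical covariates (population P, ocean age A, origin H, juvenile
history J, migration year y).

M for the Snake reach is the two-leg trapezoid
``D1*(T_BON+T_MCN)/2 + D2*(T_MCN+T_ICH)/2`` where the D are leg durations in
days between first detections and the T are the daily mean temperatures on
the day of first detection at each dam; the Salmon-reach load adds the
ICH->LGR leg.  M is log-transformed (offset 1 degree-day) and C cube-root
transformed for modeling; raw values are kept alongside.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import REACHES, CatchSeries, EnvSeries, FishRecord, ReachDef, ValidationError

__all__ = [
    "reach_conditions",
    "cumulative_temp",
    "align_catch",
    "log_degree_days",
    "cube_root",
    "transform_design",
    "build_design_table",
    "age_class",
    "correlation_screen",
    "LOG_OFFSET_DEGREE_DAYS",
]

logger = logging.getLogger(__name__)

#: Offset used in ln(M + offset); M = 0 occurs for same-day traversal.
LOG_OFFSET_DEGREE_DAYS = 1.0

_REACH_COLUMN = {"Columbia": "surv_columbia", "Snake": "surv_snake", "Salmon": "surv_salmon"}


def reach_conditions(fish: FishRecord, env: dict, reach: ReachDef) -> tuple[float, float]:
    """Temperature (degC) and flow (m3/s) assigned to a fish at reach entry.

    ``env`` maps site name to :class:`EnvSeries`.  Columbia/Snake use the
    single daily value on the entry date (window 1); the Salmon reach uses
    the arithmetic mean over the species window starting on the entry date,
    with temperature and flow possibly drawn from different gauges.
    """
    entry = fish.detections.get(reach.entry_dam)
    if entry is None:
        raise ValidationError(
            f"{fish.fish_id}: no detection at {reach.entry_dam} for reach {reach.name}"
        )
    w = reach.window(fish.species)
    t_env: EnvSeries = env[reach.temp_site]
    f_env: EnvSeries = env[reach.flow_site]
    T = t_env.window_mean("temperature", entry, w)
    F = f_env.window_mean("flow", entry, w)
    return T, F


def cumulative_temp(fish: FishRecord, env: dict, target_reach: str) -> float:
    """Degree-days accumulated from Bonneville to reach entry.

    Two-point trapezoid per dam-to-dam leg: each leg contributes the leg
    duration (days between first detections) times the mean of the entry-day
    temperatures at its two dams.  ``target_reach`` is ``"Snake"``
    (BON->MCN->ICH) or ``"Salmon"`` (additionally ICH->LGR).
    """
    if target_reach not in ("Snake", "Salmon"):
        raise ValueError(f"cumulative temperature undefined for reach {target_reach!r}")
    legs = [("BON", "MCN"), ("MCN", "ICH")]
    if target_reach == "Salmon":
        legs.append(("ICH", "LGR"))
    M = 0.0
    for a, b in legs:
        da, db = fish.detections.get(a), fish.detections.get(b)
        if da is None or db is None:
            missing = a if da is None else b
            raise ValidationError(
                f"{fish.fish_id}: missing {missing} detection for M_{target_reach}"
            )
        D = (db - da).days
        Ta = env[a].value_on("temperature", da)
        Tb = env[b].value_on("temperature", db)
        M += D * (Ta + Tb) / 2.0
    return M


def align_catch(fish: FishRecord, catch: CatchSeries) -> float:
    """Weekly Zone 6 catch in the week the fish passed Bonneville."""
    bon = fish.detections.get("BON")
    if bon is None:
        raise ValidationError(f"{fish.fish_id}: no Bonneville detection")
    return catch.catch_in_week_of(bon)


def log_degree_days(M, offset: float = LOG_OFFSET_DEGREE_DAYS):
    """ln(M + offset); the offset keeps same-day traversal (M = 0) finite."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValidationError("degree-days must be nonnegative")
    return np.log(M + offset)


def cube_root(C):
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValidationError("catch must be nonnegative")
    return np.cbrt(C)


def age_class(ocean_age: int) -> str:
    """Ocean age as an unordered factor with levels 1, 2, 3+."""
    return "3+" if ocean_age >= 3 else str(int(ocean_age))


def transform_design(design: pd.DataFrame) -> pd.DataFrame:
    """Add the modeling transforms (logM, crootC) alongside raw M and C."""
    out = design.copy()
    if "M" in out.columns:
        out["logM"] = log_degree_days(out["M"])
    if "C" in out.columns:
        out["crootC"] = cube_root(out["C"])
    return out


def build_design_table(
    records,
    env: dict,
    catch: CatchSeries | None,
    reach: ReachDef | str,
    species: str | None = None,
) -> pd.DataFrame:
    """One design row per fish that entered the reach with a known outcome.

    Fish whose covariates cannot be computed (missing intermediate
    detections for M, env coverage short of the window) are excluded and
    logged, mirroring the exclusion rules of the retrospective analysis.
    """
    if isinstance(reach, str):
        reach = REACHES[reach]
    rows, n_excluded = [], 0
    want_M = reach.name in ("Snake", "Salmon")
    want_C = reach.name == "Columbia"
    for fish in records:
        if species is not None and fish.species != species:
            continue
        state = fish.reach_survival.get(reach.name, "not_applicable")
        if state == "not_applicable" or not fish.entered(reach):
            continue
        try:
            T, F = reach_conditions(fish, env, reach)
            row = {
                "fish_id": fish.fish_id,
                "species": fish.species,
                "reach": reach.name,
                "T": T,
                "F": F,
                "population": fish.population,
                "run": fish.run or "",
                "A": age_class(fish.ocean_age),
                "H": fish.origin,
                "J": fish.juv_history,
                "year": fish.migration_year,
                "S": 1 if state == "survived" else 0,
            }
            if want_M:
                row["M"] = cumulative_temp(fish, env, reach.name)
            if want_C:
                if catch is None:
                    raise ValidationError("catch series required for Columbia reach")
                row["C"] = align_catch(fish, catch)
            rows.append(row)
        except ValidationError as exc:
            n_excluded += 1
            logger.info("excluded %s from %s design: %s", fish.fish_id, reach.name, exc)
    if n_excluded:
        logger.warning(
            "%s reach: excluded %d fish with incomputable covariates",
            reach.name, n_excluded,
        )
    design = pd.DataFrame(rows)
    if design.empty:
        return design
    return transform_design(design)


def correlation_screen(design: pd.DataFrame, cols) -> pd.DataFrame:
    """Pairwise Pearson correlations among continuous covariates.

    Used to enforce the collinearity rule: smooth covariates may be combined
    in one model only when every pairwise |r| is below 0.7.
    """
    cols = [c for c in cols if c in design.columns]
    return design[cols].corr(method="pearson")
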