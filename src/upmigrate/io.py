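"""Domain types and tabular IO for tag records, environmental series, and catch.

The migration route is discretized at the mainstem dams where PIT-tag
detections occur: Bonneville (BON), McNary (MCN), Ice Harbor (ICH), Lower
Granite (LGR), and a terminal site (weir or hatchery trap) in the Salmon
River basin.  Survival is scored through three reaches: Columbia (BON->ICH),
Snake (ICH->LGR) and the free-flowing Salmon reach (LGR->terminal).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "ROUTE",
    "REACHES",
    "SPECIES",
    "FishRecord",
    "EnvSeries",
    "ReachDef",
    "CatchSeries",
    "ValidationError",
    "read_fish_table",
    "write_fish_table",
    "read_env_series",
    "write_env_series",
    "read_catch_series",
    "write_catch_series",
    "fill_missing_env",
]

#: Detection sites in downstream-to-upstream order.
ROUTE = ("BON", "MCN", "ICH", "LGR", "TERM")

SPECIES = ("chinook", "sockeye")

_SURV_LEVELS = ("survived", "died", "not_applicable")
_ORIGINS = ("hatchery", "wild")
_JUV = ("transported", "in_river")
_RUNS = ("spring", "summer")


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


@dataclass
class ReachDef:
    """A survival reach: entry dam, exit site, and environmental conventions.

    ``window_days`` maps species to the averaging window (days, starting on
    the reach-entry date) for temperature and flow.  In the impounded
    Columbia and Snake reaches entry-day conditions are representative
    (window 1); in the long free-flowing Salmon reach conditions are averaged
    over 1 week for Chinook and 2 weeks for sockeye.  ``temp_site`` and
    ``flow_site`` name the gauges used, which differ in the Salmon reach.
    """

    name: str
    entry_dam: str
    exit_site: str
    temp_site: str
    flow_site: str
    window_days: dict = field(default_factory=lambda: {"chinook": 1, "sockeye": 1})

    def __post_init__(self):
        if any(w < 1 for w in self.window_days.values()):
            raise ValidationError(f"reach {self.name}: window_days must be >= 1")

    def window(self, species: str) -> int:
        return int(self.window_days[species])


#: Default reach definitions.  Salmon-reach gauge roles (Anatone for
#: temperature, Whitebird for flow) are configuration, not hard-coded in
#: model code.
REACHES = {
    "Columbia": ReachDef("Columbia", "BON", "ICH", "BON", "BON"),
    "Snake": ReachDef("Snake", "ICH", "LGR", "ICH", "ICH"),
    "Salmon": ReachDef(
        "Salmon", "LGR", "TERM", "ANATONE", "WHITEBIRD",
        window_days={"chinook": 7, "sockeye": 14},
    ),
}

REACH_ORDER = ("Columbia", "Snake", "Salmon")


@dataclass
class FishRecord:
    """One PIT-tagged adult: identity, covariates, detections, outcomes.

    ``detections`` maps site name (subset of :data:`ROUTE`) to detection
    date; ``reach_survival`` maps reach name to one of ``survived``,
    ``died``, ``not_applicable``.
    """

    fish_id: str
    species: str
    population: str
    run: str | None
    ocean_age: int
    origin: str
    juv_history: str
    migration_year: int
    detections: dict
    reach_survival: dict

    def validate(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"{self.fish_id}: unknown species {self.species!r}")
        if self.origin not in _ORIGINS:
            raise ValidationError(f"{self.fish_id}: unknown origin {self.origin!r}")
        if self.juv_history not in _JUV:
            raise ValidationError(
                f"{self.fish_id}: unknown juvenile history {self.juv_history!r}"
            )
        if self.run is not None and self.run not in _RUNS:
            raise ValidationError(f"{self.fish_id}: unknown run {self.run!r}")
        if self.ocean_age < 1:
            raise ValidationError(f"{self.fish_id}: ocean_age must be >= 1")
        # Detection dates weakly increasing along the route.
        prev_site, prev_date = None, None
        for site in ROUTE:
            d = self.detections.get(site)
            if d is None:
                continue
            if prev_date is not None and d < prev_date:
                raise ValidationError(
                    f"{self.fish_id}: detection at {site} ({d}) precedes "
                    f"{prev_site} ({prev_date})"
                )
            prev_site, prev_date = site, d
        for reach, state in self.reach_survival.items():
            if state not in _SURV_LEVELS:
                raise ValidationError(
                    f"{self.fish_id}: bad survival state {state!r} for {reach}"
                )
        # A detection upstream of a reach implies survival of that reach.
        for reach, rd in REACHES.items():
            exit_idx = ROUTE.index(rd.exit_site)
            seen_upstream = any(
                self.detections.get(site) is not None for site in ROUTE[exit_idx:]
            )
            if seen_upstream and self.reach_survival.get(reach) == "died":
                raise ValidationError(
                    f"{self.fish_id}: detected upstream of reach {reach} "
                    "but marked died"
                )

    def entered(self, reach: ReachDef) -> bool:
        return self.detections.get(reach.entry_dam) is not None


@dataclass
class EnvSeries:
    """Date-indexed daily mean temperature (degC) and flow (m3/s) at a site.

    ``data`` is a DataFrame indexed by contiguous daily DatetimeIndex with
    columns ``temperature`` and ``flow``; gaps are NaN until filled.
    """

    site: str
    scenario: str
    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if not df.index.is_monotonic_increasing:
            df = df.sort_index()
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique()
            raise ValidationError(
                f"{self.site}: duplicate dates {[str(d.date()) for d in dups[:5]]}"
            )
        # Reindex to a contiguous daily grid; absent days become NaN gaps.
        full = pd.date_range(df.index.min(), df.index.max(), freq="D")
        df = df.reindex(full)
        df.index.name = "date"
        if (df["flow"].dropna() < 0).any():
            raise ValidationError(f"{self.site}: negative flow values")
        self.data = df[["temperature", "flow"]]

    # -- accessors ---------------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def temperature(self) -> pd.Series:
        return self.data["temperature"]

    @property
    def flow(self) -> pd.Series:
        return self.data["flow"]

    def gaps(self) -> pd.DataFrame:
        """Runs of missing days per variable: columns variable, start, end, length."""
        rows = []
        for var in ("temperature", "flow"):
            isna = self.data[var].isna().to_numpy()
            i = 0
            while i < len(isna):
                if isna[i]:
                    j = i
                    while j + 1 < len(isna) and isna[j + 1]:
                        j += 1
                    rows.append(
                        {
                            "variable": var,
                            "start": self.dates[i],
                            "end": self.dates[j],
                            "length": j - i + 1,
                        }
                    )
                    i = j + 1
                else:
                    i += 1
        return pd.DataFrame(rows, columns=["variable", "start", "end", "length"])

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    def value_on(self, var: str, when) -> float:
        when = pd.Timestamp(when)
        if when not in self.data.index:
            raise ValidationError(
                f"{self.site}: no {var} coverage for {when.date()}"
            )
        return float(self.data.loc[when, var])

    def window_mean(self, var: str, start, window: int) -> float:
        """Mean of ``var`` over ``window`` days starting on ``start``."""
        start = pd.Timestamp(start)
        end = start + timedelta(days=window - 1)
        if start < self.dates[0] or end > self.dates[-1]:
            raise ValidationError(
                f"{self.site}: {var} coverage short of window "
                f"{start.date()}..{end.date()}"
            )
        chunk = self.data.loc[start:end, var]
        if chunk.isna().any():
            raise ValidationError(
                f"{self.site}: missing {var} inside window "
                f"{start.date()}..{end.date()}"
            )
        return float(chunk.mean())

    def copy(self) -> "EnvSeries":
        return EnvSeries(self.site, self.scenario, self.data.copy())


@dataclass
class CatchSeries:
    """Weekly fishery catch in the lower Columbia (Zone 6).

    ``data`` is a Series of nonnegative weekly totals indexed by week-start
    date (spacing 7 days).
    """

    data: pd.Series

    def __post_init__(self):
        s = self.data.sort_index()
        if (s < 0).any():
            raise ValidationError("catch values must be nonnegative")
        deltas = np.diff(s.index.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 7):
            raise ValidationError("catch series must be weekly (7-day spacing)")
        self.data = s

    @classmethod
    def from_period_totals(cls, starts, ends, totals) -> "CatchSeries":
        """Disaggregate multi-week reporting periods into weekly estimates.

        A total reported for a period spanning w whole weeks is spread
        linearly (evenly) across those weeks, as done for hook-and-line
        fisheries reported over longer intervals.
        """
        weekly = {}
        for s, e, tot in zip(starts, ends, totals):
            s, e = pd.Timestamp(s), pd.Timestamp(e)
            n_weeks = int(((e - s).days + 1) / 7)
            if n_weeks < 1 or (e - s).days + 1 != 7 * n_weeks:
                raise ValidationError(
                    f"period {s.date()}..{e.date()} is not a whole number of weeks"
                )
            for i in range(n_weeks):
                wk = s + timedelta(days=7 * i)
                weekly[wk] = weekly.get(wk, 0.0) + tot / n_weeks
        return cls(pd.Series(weekly).sort_index())

    def week_of(self, when) -> pd.Timestamp:
        """Week-start containing ``when``; raises if not covered."""
        when = pd.Timestamp(when)
        idx = self.data.index
        pos = idx.searchsorted(when, side="right") - 1
        if pos < 0 or when - idx[pos] > timedelta(days=6):
            raise ValidationError(f"catch series does not cover {when.date()}")
        return idx[pos]

    def catch_in_week_of(self, when) -> float:
        return float(self.data.loc[self.week_of(when)])


# ---------------------------------------------------------------------------
# Fish table IO
# ---------------------------------------------------------------------------

_FISH_COLUMNS = [
    "fish_id", "species", "population", "run", "ocean_age", "origin",
    "juv_history", "migration_year", "date_BON", "date_MCN", "date_ICH",
    "date_LGR", "date_TERM", "surv_columbia", "surv_snake", "surv_salmon",
]

_REACH_COL = {"Columbia": "surv_columbia", "Snake": "surv_snake", "Salmon": "surv_salmon"}


def _parse_date(text) -> date | None:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return None
    try:
        return pd.Timestamp(text).date()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"malformed date {text!r}") from exc


def read_fish_table(path) -> list[FishRecord]:
    """Read a fish CSV into validated :class:`FishRecord` objects.

    Any row violating the record invariants is rejected; a single
    :class:`ValidationError` is raised listing each offending line number
    (1-based, counting the header as line 1) and fish id.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _FISH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"fish table missing columns: {missing}")
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        try:
            detections = {}
            for site in ROUTE:
                d = _parse_date(getattr(row, f"date_{site}"))
                if d is not None:
                    detections[site] = d
            rec = FishRecord(
                fish_id=row.fish_id,
                species=row.species,
                population=row.population,
                run=row.run or None,
                ocean_age=int(row.ocean_age),
                origin=row.origin,
                juv_history=row.juv_history,
                migration_year=int(row.migration_year),
                detections=detections,
                reach_survival={
                    reach: getattr(row, col) or "not_applicable"
                    for reach, col in _REACH_COL.items()
                },
            )
            rec.validate()
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {line_no} (fish_id={row.fish_id!r}): {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid rows in fish table:\n" + "\n".join(problems)
        )
    return records


def fish_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "fish_id": r.fish_id,
            "species": r.species,
            "population": r.population,
            "run": r.run or "",
            "ocean_age": r.ocean_age,
            "origin": r.origin,
            "juv_history": r.juv_history,
            "migration_year": r.migration_year,
        }
        for site in ROUTE:
            d = r.detections.get(site)
            row[f"date_{site}"] = d.isoformat() if d is not None else ""
        for reach, col in _REACH_COL.items():
            row[col] = r.reach_survival.get(reach, "not_applicable")
        rows.append(row)
    return pd.DataFrame(rows, columns=_FISH_COLUMNS)


def write_fish_table(records, path) -> None:
    fish_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Environmental series IO
# ---------------------------------------------------------------------------

def read_env_series(path) -> EnvSeries:
    """Read one site/scenario env CSV (date,site,scenario,temp_C,flow_m3s)."""
    df = pd.read_csv(path, parse_dates=["date"], float_precision="round_trip")
    for col in ("date", "site", "scenario", "temp_C", "flow_m3s"):
        if col not in df.columns:
            raise ValidationError(f"env table missing column {col!r}")
    sites = df["site"].unique()
    scens = df["scenario"].unique()
    if len(sites) != 1 or len(scens) != 1:
        raise ValidationError(
            f"env file must hold one site/scenario, got {list(sites)}/{list(scens)}"
        )
    data = df.set_index("date")[["temp_C", "flow_m3s"]].rename(
        columns={"temp_C": "temperature", "flow_m3s": "flow"}
    )
    return EnvSeries(site=str(sites[0]), scenario=str(scens[0]), data=data)


def write_env_series(env: EnvSeries, path) -> None:
    out = env.data.rename(columns={"temperature": "temp_C", "flow": "flow_m3s"})
    out = out.reset_index().rename(columns={"index": "date"})
    out.insert(1, "site", env.site)
    out.insert(2, "scenario", env.scenario)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_catch_series(path) -> CatchSeries:
    df = pd.read_csv(path, parse_dates=["week_start"])
    if "catch" not in df.columns:
        raise ValidationError("catch table missing column 'catch'")
    return CatchSeries(df.set_index("week_start")["catch"].astype(float))


def write_catch_series(catch: CatchSeries, path) -> None:
    out = catch.data.rename("catch").reset_index()
    out.columns = ["week_start", "catch"]
    out["week_start"] = out["week_start"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def fill_missing_env(
    target: EnvSeries,
    neighbor: EnvSeries | None = None,
    max_interp_days: int = 3,
) -> EnvSeries:
    """Fill gaps in ``target`` by interpolation or regression on a neighbor.

    Interior gaps of at most ``max_interp_days`` days are filled by linear
    interpolation between the bracketing observed values.  Longer gaps (and
    gaps at the series edges) are filled from an ordinary least-squares
    regression of target on ``neighbor``, fit over days where both are
    complete.  Observed values are never altered; the result has no gaps.
    """
    out = target.data.copy()
    gaps = target.gaps()
    if gaps.empty:
        return EnvSeries(target.site, target.scenario, out)

    for var in ("temperature", "flow"):
        col = out[var]
        var_gaps = gaps[gaps["variable"] == var]
        if var_gaps.empty:
            continue
        interp = col.interpolate(method="time", limit_area="inside")
        fit = None
        for g in var_gaps.itertuples(index=False):
            span = pd.date_range(g.start, g.end, freq="D")
            interior = g.start > col.first_valid_index() and g.end < col.last_valid_index()
            if g.length <= max_interp_days and interior:
                out.loc[span, var] = interp.loc[span]
                continue
            # Regression route.
            if neighbor is None:
                raise ValidationError(
                    f"{target.site}: {var} gap {g.start.date()}..{g.end.date()} "
                    f"exceeds {max_interp_days} d and no neighbor series given"
                )
            if fit is None:
                nb = neighbor.data[var].reindex(col.index)
                both = col.notna() & nb.notna()
                if both.sum() < 3:
                    raise ValidationError(
                        f"{target.site}: too few shared complete days with "
                        f"{neighbor.site} to regress {var}"
                    )
                slope, intercept = np.polyfit(nb[both], col[both], 1)
                fit = (slope, intercept, nb)
            slope, intercept, nb = fit
            pred = intercept + slope * nb.loc[span]
            if pred.isna().any():
                bad = span[pred.isna().to_numpy()]
                raise ValidationError(
                    f"{target.site}: {var} gap not coverable — neighbor "
                    f"{neighbor.site} missing on "
                    f"{bad[0].date()}..{bad[-1].date()}"
                )
            out.loc[span, var] = pred
        if var == "flow":
            out[var] = out[var].clip(lower=0.0)
    filled = EnvSeries(target.site, target.scenario, out)
    assert filled.is_complete()
    return filled
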