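"""Design-table covariates: reach conditions, degree-days, catch, transforms."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upmigrate.covariates import (
    align_catch,
    build_design_table,
    correlation_screen,
    cube_root,
    cumulative_temp,
    log_degree_days,
    reach_conditions,
    transform_design,
)
from upmigrate.io import REACHES, CatchSeries, EnvSeries, FishRecord, ValidationError


def _env(site, temps, start="2010-07-01", flow=1000.0):
    idx = pd.date_range(start, periods=len(temps), freq="D")
    return EnvSeries(
        site, "observed",
        pd.DataFrame({"temperature": temps, "flow": flow}, index=idx),
    )


def _fish(species="sockeye", **detections):
    return FishRecord(
        "F1", species, "Sawtooth" if species == "sockeye" else "Imnaha",
        None if species == "sockeye" else "summer", 2, "hatchery", "in_river",
        2010, detections, {},
    )


class TestReachConditions:
    def test_constant_series_any_window(self):
        env = {"ANATONE": _env("ANATONE", [15.0] * 30),
               "WHITEBIRD": _env("WHITEBIRD", [15.0] * 30, flow=300.0)}
        fish = _fish(LGR=date(2010, 7, 5))
        T, F = reach_conditions(fish, env, REACHES["Salmon"])
        assert T == pytest.approx(15.0)
        assert F == pytest.approx(300.0)

    def test_sockeye_14_day_mean(self):
        temps = [10.0] * 7 + [20.0] * 7
        env = {"ANATONE": _env("ANATONE", temps),
               "WHITEBIRD": _env("WHITEBIRD", temps)}
        fish = _fish(LGR=date(2010, 7, 1))
        T, _ = reach_conditions(fish, env, REACHES["Salmon"])
        assert T == pytest.approx(15.0)

    def test_chinook_7_day_mean_of_rising_series(self):
        temps = [10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0]
        env = {"ANATONE": _env("ANATONE", temps),
               "WHITEBIRD": _env("WHITEBIRD", temps)}
        fish = _fish(species="chinook", LGR=date(2010, 7, 1))
        T, _ = reach_conditions(fish, env, REACHES["Salmon"])
        assert T == pytest.approx(13.0)

    def test_entry_day_value_in_columbia(self):
        temps = list(np.linspace(10, 20, 11))
        env = {"BON": _env("BON", temps)}
        fish = _fish(BON=date(2010, 7, 4))
        T, _ = reach_conditions(fish, env, REACHES["Columbia"])
        assert T == pytest.approx(temps[3])

    def test_coverage_short_of_window_errors(self):
        env = {"ANATONE": _env("ANATONE", [15.0] * 5),
               "WHITEBIRD": _env("WHITEBIRD", [15.0] * 5)}
        fish = _fish(LGR=date(2010, 7, 3))
        with pytest.raises(ValidationError, match="short of window"):
            reach_conditions(fish, env, REACHES["Salmon"])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        temps = list(rng.uniform(8, 20, 20))
        fish = _fish(LGR=date(2010, 7, 2))
        base = {"ANATONE": _env("ANATONE", temps),
                "WHITEBIRD": _env("WHITEBIRD", temps)}
        shifted = {"ANATONE": _env("ANATONE", [t + 2.5 for t in temps]),
                   "WHITEBIRD": _env("WHITEBIRD", temps)}
        T0, _ = reach_conditions(fish, base, REACHES["Salmon"])
        T1, _ = reach_conditions(fish, shifted, REACHES["Salmon"])
        assert T1 - T0 == pytest.approx(2.5)


def _dam_envs(tb, tm, ti, tl=18.0, start="2010-07-01"):
    """Constant-temperature series per dam (values at detection read back)."""
    n = 40
    return {
        "BON": _env("BON", [tb] * n, start),
        "MCN": _env("MCN", [tm] * n, start),
        "ICH": _env("ICH", [ti] * n, start),
        "LGR": _env("LGR", [tl] * n, start),
    }


class TestCumulativeTemp:
    def test_direct_two_leg_arithmetic(self):
        # D1=2 at (12+14)/2 plus D2=1 at (14+16)/2 -> 41 degree-days
        env = _dam_envs(12.0, 14.0, 16.0)
        fish = _fish(
            BON=date(2010, 7, 1), MCN=date(2010, 7, 3), ICH=date(2010, 7, 4)
        )
        assert cumulative_temp(fish, env, "Snake") == pytest.approx(41.0)

    def test_zero_duration_third_leg(self):
        env = _dam_envs(12.0, 14.0, 16.0)
        fish = _fish(
            BON=date(2010, 7, 1), MCN=date(2010, 7, 3),
            ICH=date(2010, 7, 4), LGR=date(2010, 7, 4),
        )
        m_snake = cumulative_temp(fish, env, "Snake")
        assert cumulative_temp(fish, env, "Salmon") == pytest.approx(m_snake)

    def test_missing_intermediate_detection_errors(self):
        env = _dam_envs(12.0, 14.0, 16.0)
        fish = _fish(BON=date(2010, 7, 1), ICH=date(2010, 7, 4))
        with pytest.raises(ValidationError, match="MCN"):
            cumulative_temp(fish, env, "Snake")

    def test_matches_daily_trapezoid_oracle(self):
        """Leg-by-leg two-point formula equals a day-by-day trapezoid that
        linearly interpolates temperature between dam-passage snapshots."""
        rng = np.random.default_rng(42)
        env = {
            site: _env(site, list(rng.uniform(10, 22, 60)))
            for site in ("BON", "MCN", "ICH", "LGR")
        }
        for _ in range(20):
            d0 = date(2010, 7, 1)
            offsets = np.sort(rng.choice(np.arange(0, 25), size=4, replace=False))
            dets = {
                s: d0 + pd.Timedelta(days=int(o)).to_pytimedelta()
                for s, o in zip(("BON", "MCN", "ICH", "LGR"), offsets)
            }
            fish = _fish(**{k: v for k, v in dets.items()})
            # oracle: daily linear interpolation between snapshots, trapezoid sum
            sites = ["BON", "MCN", "ICH", "LGR"]
            t_knots = [float(offsets[i]) for i in range(4)]
            T_knots = [
                env[s].value_on("temperature", dets[s]) for s in sites
            ]
            grid = np.linspace(t_knots[0], t_knots[-1], 2000)
            path = np.interp(grid, t_knots, T_knots)
            oracle = np.trapezoid(path, grid)
            assert cumulative_temp(fish, env, "Salmon") == pytest.approx(
                oracle, rel=1e-6
            )


class TestCatchAndTransforms:
    def test_catch_in_passage_week(self):
        idx = pd.date_range("2010-06-28", periods=4, freq="7D")
        cs = CatchSeries(pd.Series([125.0, 60.0, 30.0, 5.0], index=idx))
        fish = _fish(BON=date(2010, 7, 2))
        assert align_catch(fish, cs) == 125.0

    def test_cube_root_values(self):
        assert cube_root(27.0) == pytest.approx(3.0)
        assert cube_root(0.0) == 0.0

    def test_log_degree_days_offset(self):
        assert log_degree_days(41.0) == pytest.approx(np.log(42.0))
        assert np.isfinite(log_degree_days(0.0))

    @given(st.floats(min_value=0, max_value=1e4))
    @settings(max_examples=30, deadline=None)
    def test_cube_root_inverts(self, c):
        assert cube_root(c) ** 3 == pytest.approx(c, rel=1e-9, abs=1e-9)


class TestDesignTable:
    def test_rows_only_for_entered_fish_with_known_outcome(
        self, sockeye_cohort, obs_env, catch_series
    ):
        records, _ = sockeye_cohort
        design = build_design_table(
            records, obs_env, catch_series, "Snake", species="sockeye"
        )
        n_known = sum(
            1 for r in records if r.reach_survival["Snake"] != "not_applicable"
        )
        assert 0 < len(design) <= n_known
        assert set(design["S"].unique()) <= {0, 1}
        assert {"T", "F", "M", "logM"} <= set(design.columns)
        np.testing.assert_allclose(
            design["logM"], np.log(design["M"] + 1.0)
        )
        assert (design["M"] >= 0).all()

    def test_m_salmon_at_least_m_snake(self, sockeye_cohort, obs_env, catch_series):
        records, _ = sockeye_cohort
        snake = build_design_table(records, obs_env, catch_series, "Snake",
                                   species="sockeye").set_index("fish_id")
        salmon = build_design_table(records, obs_env, catch_series, "Salmon",
                                    species="sockeye").set_index("fish_id")
        shared = snake.index.intersection(salmon.index)
        assert len(shared) > 50
        assert (salmon.loc[shared, "M"] >= snake.loc[shared, "M"] - 1e-9).all()

    def test_correlation_screen_symmetric_bounded(
        self, sockeye_cohort, obs_env, catch_series
    ):
        records, _ = sockeye_cohort
        design = build_design_table(records, obs_env, catch_series, "Snake",
                                    species="sockeye")
        corr = correlation_screen(design, ["T", "F", "logM"])
        np.testing.assert_allclose(corr, corr.T)
        assert (corr.abs() <= 1.0 + 1e-12).all().all()

    def test_transform_design_adds_columns(self):
        df = pd.DataFrame({"M": [41.0], "C": [27.0]})
        out = transform_design(df)
        assert out["logM"].iloc[0] == pytest.approx(np.log(42.0))
        assert out["crootC"].iloc[0] == pytest.approx(3.0)
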