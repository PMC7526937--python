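"""Sensitivity operators (arrival shift, temperature delta, flow factor) and grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upmigrate.io import EnvSeries, ValidationError
from upmigrate.sensitivity import (
    SensitivitySpec,
    add_delta_temperature,
    apply_flow_factor,
    shift_arrivals,
)


def _env(temps, flows, site="BON", scenario="historical", start="2010-01-01"):
    idx = pd.date_range(start, periods=len(temps), freq="D")
    return EnvSeries(
        site, scenario,
        pd.DataFrame({"temperature": temps, "flow": flows}, index=idx),
    )


class TestShift:
    def test_examples(self):
        assert shift_arrivals([180], 14)[0] == 166
        np.testing.assert_allclose(shift_arrivals([180, 190], 0), [180, 190])

    def test_mean_shifts_linearly(self):
        days = np.random.default_rng(0).normal(180, 6, 1000)
        assert shift_arrivals(days, 9).mean() == pytest.approx(days.mean() - 9)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            shift_arrivals([180], -3)


class TestTempDelta:
    def test_identity_and_constant_shift(self):
        env = _env([15.0] * 5, [100.0] * 5)
        same = add_delta_temperature(env, 0.0)
        pd.testing.assert_frame_equal(same.data, env.data)
        warm = add_delta_temperature(env, 2.0)
        np.testing.assert_allclose(warm.temperature, 17.0)
        np.testing.assert_allclose(warm.flow, 100.0)

    def test_inverse(self):
        env = _env(list(np.linspace(5, 20, 10)), [100.0] * 10)
        back = add_delta_temperature(add_delta_temperature(env, 0.4), -0.4)
        np.testing.assert_allclose(back.temperature, env.temperature, atol=1e-12)


class TestFlowFactor:
    def test_factor_zero_is_historical(self):
        hist = _env([10] * 4, [100.0, 200.0, 300.0, 400.0])
        scen = _env([12] * 4, [80.0, 150.0, 250.0, 500.0], scenario="dry")
        out = apply_flow_factor(hist, scen, 0.0)
        np.testing.assert_allclose(out.flow, hist.flow)

    def test_factor_one_is_scenario(self):
        hist = _env([10] * 4, [100.0, 200.0, 300.0, 400.0])
        scen = _env([12] * 4, [80.0, 150.0, 250.0, 500.0], scenario="dry")
        out = apply_flow_factor(hist, scen, 1.0)
        np.testing.assert_allclose(out.flow, scen.flow)

    def test_floor_binds_when_affine_value_below(self):
        hist = _env([10.0], [20.0])
        scen = _env([10.0], [5.0], scenario="dry")
        out = apply_flow_factor(hist, scen, 1.4, floor=10.0)
        # 20 + (5 - 20) * 1.4 = -1 -> floored at 10
        assert out.flow.iloc[0] == pytest.approx(10.0)

    def test_midpoint_interpolation_above_floor(self):
        hist = _env([10] * 3, [100.0, 200.0, 300.0])
        scen = _env([10] * 3, [200.0, 100.0, 500.0], scenario="wet")
        out = apply_flow_factor(hist, scen, 0.5)
        np.testing.assert_allclose(out.flow, [150.0, 150.0, 400.0])

    def test_date_mismatch_errors(self):
        hist = _env([10] * 3, [100.0] * 3)
        scen = _env([10] * 4, [100.0] * 4, scenario="dry")
        with pytest.raises(ValidationError, match="date mismatch"):
            apply_flow_factor(hist, scen, 0.5)

    @given(st.floats(min_value=0.0, max_value=1.4),
           st.floats(min_value=15.0, max_value=500.0),
           st.floats(min_value=15.0, max_value=500.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_in_factor_above_floor(self, fx, fh, fs):
        hist = _env([10.0], [fh])
        scen = _env([10.0], [fs], scenario="dry")
        out = apply_flow_factor(hist, scen, fx).flow.iloc[0]
        affine = fh + (fs - fh) * fx
        assert out == pytest.approx(max(affine, 10.0))

    def test_commutes_with_temperature_delta(self):
        hist = _env(list(np.linspace(8, 20, 6)), list(np.linspace(50, 400, 6)))
        scen = _env(list(np.linspace(9, 22, 6)), list(np.linspace(30, 350, 6)),
                    scenario="dry")
        a = add_delta_temperature(apply_flow_factor(hist, scen, 0.7), 1.2)
        b = apply_flow_factor(hist, add_delta_temperature(scen, 1.2), 0.7)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestSpec:
    def test_defaults_are_published_grid(self):
        spec = SensitivitySpec()
        assert spec.arrival_shifts_days == (3, 6, 9, 12, 14)
        assert spec.temp_deltas_C == (-0.8, -0.4, 0.4, 0.8, 1.2, 1.6, 2.0)
        assert spec.flow_factors == (0.0, 0.2, 0.4, 0.6, 0.8, 1.2, 1.4)
        assert spec.flow_floor == 10.0

    def test_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            SensitivitySpec(flow_floor=0.0)


@pytest.fixture(scope="module")
def grid_inputs(gen_config, obs_env, sockeye_cohort):
    from upmigrate.arrival import ArrivalTimingModel, annual_covariates
    from upmigrate.projection import SimulationConfig
    from upmigrate.io import REACH_ORDER
    from tests.test_projection import _flat_predictor, _rates

    records, _ = sockeye_cohort
    cov = annual_covariates(obs_env["BON"])
    days = np.array([r.detections["BON"].timetuple().tm_yday for r in records])
    years = np.array([r.migration_year for r in records])
    arr = ArrivalTimingModel(days, years, cov, ("temp_Apr",), 1).fit(
        n_restarts=2, seed=0
    )
    # survival depends monotonically on temperature only
    from upmigrate.smoothing import ThinPlateBasis
    from upmigrate.survival import SurvivalPredictor

    t_grid = np.linspace(8, 30, 80)
    basis = ThinPlateBasis(t_grid, 4)
    X = basis.transform(t_grid)
    target_logit = 2.0 - 0.35 * np.maximum(t_grid - 15.0, 0.0)
    coef, *_ = np.linalg.lstsq(
        np.column_stack([np.ones_like(t_grid), X]), target_logit, rcond=None
    )
    preds = {
        ("sockeye", r): SurvivalPredictor(
            species="sockeye", reach=r, smooth_terms=("T",),
            factor_terms=(), bases={"T": basis}, factor_levels={},
            n_year_cols=0, beta=coef, cov=np.zeros((len(coef),) * 2),
            coef_names=["i"] + [f"s(T).{i}" for i in range(X.shape[1])],
            baseline_population="Sawtooth",
            hull_points=np.column_stack(
                [np.linspace(8, 30, 10), np.linspace(50, 5000, 10)]
            ),
        )
        for r in REACH_ORDER
    }
    cfg = SimulationConfig(
        n_fish_per_year=60, n_loops=1, n_years=2,
        scenarios=("historical", "dry"), species=("sockeye",), master_seed=5,
    )
    envs = {"historical": obs_env, "dry": obs_env}
    return arr, preds, envs, {"sockeye": _rates()}, cfg


class TestGrid:
    def test_empty_grid_returns_base_only(self, grid_inputs):
        from upmigrate.sensitivity import run_sensitivity_grid

        arr, preds, envs, rates, cfg = grid_inputs
        out = run_sensitivity_grid(
            SensitivitySpec(), {"sockeye": arr}, preds, envs, rates, cfg, axes=(),
        )
        assert set(out["axis"]) == {"base"}

    def test_grid_size_and_monotone_temperature_response(self, grid_inputs):
        from upmigrate.sensitivity import run_sensitivity_grid

        arr, preds, envs, rates, cfg = grid_inputs
        spec = SensitivitySpec(temp_deltas_C=(-1.0, 1.0, 3.0))
        out = run_sensitivity_grid(
            spec, {"sockeye": arr}, preds, envs, rates, cfg, axes=("temp",),
        )
        assert set(out["axis"]) == {"base", "temp"}
        assert sorted(out.loc[out.axis == "temp", "value"].unique()) == [-1.0, 1.0, 3.0]
        # survival is generated from a truth that declines above 15 degC, so
        # warming deltas must not increase survival (common random numbers)
        sub = out[(out.axis == "temp") & (out.reach == "cumulative")
                  & (out.scenario == "dry") & (out.component == "aggregate")]
        vals = sub.sort_values("value")["mean"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)
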