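"""Arrival-day phenology models: AICc, mixture fitting, selection, simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from upmigrate.arrival import (
    ArrivalTimingModel,
    ArrivalTimingResults,
    aicc,
    annual_covariates,
    qq_correlation,
    select_arrival_model,
)

YEARS = np.arange(2004, 2016)


def _cov(values, name="temp_Apr", extra=None):
    df = pd.DataFrame({name: values}, index=YEARS[: len(values)])
    df.index.name = "year"
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def _simulate(rng, beta0, beta1, sigma, cov, n_per_year, metric="temp_Apr"):
    days, years = [], []
    for y in cov.index:
        mu = beta0 + beta1 * cov.loc[y, metric]
        days.append(rng.normal(mu, sigma, n_per_year))
        years.append(np.full(n_per_year, y))
    return np.concatenate(days), np.concatenate(years)


class TestAicc:
    def test_closed_form(self):
        assert aicc(-5.0, 2, 10) == pytest.approx(14 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert aicc(-5.0, 2, 10**9) == pytest.approx(14.0, abs=1e-6)

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 2, 3)

    def test_matches_independent_formula_on_random_tuples(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ll = rng.normal(-100, 30)
            k = int(rng.integers(1, 10))
            n = int(rng.integers(k + 2, 500))
            # textbook route: AIC plus the small-sample correction term
            aic = 2 * k - 2 * ll
            oracle = aic + (2 * k * k + 2 * k) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(oracle)


class TestFitArrival:
    def test_single_year_flags_unidentified_slope(self):
        rng = np.random.default_rng(1)
        days = rng.normal(160, 5, 500)
        years = np.full(500, 2010)
        cov = pd.DataFrame({"temp_Apr": [9.0]}, index=[2010])
        res = ArrivalTimingModel(days, years, cov, ("temp_Apr",), 1).fit(
            n_restarts=3, seed=0
        )
        assert not res.model.slope_identified[0]
        p = res.params
        assert p["beta0_1"] == pytest.approx(160, abs=1.0)
        assert p["sigma_1"] == pytest.approx(5, abs=0.5)
        assert p["beta1_1"] == 0.0

    def test_two_component_recovery_within_ci(self):
        rng = np.random.default_rng(2)
        temps = rng.normal(9.0, 1.2, 12)
        flows = rng.normal(5.0, 0.8, 12)
        cov = _cov(temps, extra={"flow_Apr": flows})
        true = {"b0": (134.0, 159.0), "b1": (-3.0, 0.5), "sigma": (8.0, 10.0), "p": 0.4}
        days, years = [], []
        for i, y in enumerate(YEARS):
            n = 2000
            comp = rng.random(n) < true["p"]
            mu = np.where(
                comp,
                true["b0"][0] + true["b1"][0] * temps[i],
                true["b0"][1] + true["b1"][1] * flows[i],
            )
            sd = np.where(comp, true["sigma"][0], true["sigma"][1])
            days.append(rng.normal(mu, sd))
            years.append(np.full(n, y))
        days, years = np.concatenate(days), np.concatenate(years)
        res = ArrivalTimingModel(
            days, years, cov, ("temp_Apr", "flow_Apr"), 2
        ).fit(n_restarts=6, seed=0)
        p, se = res.params, res.bse
        for name, truth in [
            ("beta0_1", 134.0), ("beta0_2", 159.0),
            ("beta1_1", -3.0), ("beta1_2", 0.5),
            ("sigma_1", 8.0), ("sigma_2", 10.0), ("p_spring", 0.4),
        ]:
            assert abs(p[name] - truth) < 1.96 * se[name] + 1e-9, (
                f"{name}: {p[name]:.3f} vs {truth} (se {se[name]:.3f})"
            )

    def test_selected_loglik_dominates_nested_fit(self):
        rng = np.random.default_rng(3)
        cov = _cov(rng.normal(9, 1.2, 12))
        days, years = _simulate(rng, 195.0, -1.36, 6.0, cov, 300)
        full = ArrivalTimingModel(days, years, cov, ("temp_Apr",), 1).fit(seed=0)
        # nested special case: no covariate effect (constant metric)
        cov0 = _cov(np.full(12, 9.0))
        null = ArrivalTimingModel(days, years, cov0, ("temp_Apr",), 1).fit(seed=0)
        assert full.loglik >= null.loglik - 1e-6

    def test_mixture_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        cov = _cov(rng.normal(9, 1.2, 12), extra={"flow_Apr": 5.0})
        days, years = _simulate(rng, 150.0, -3.0, 8.0, cov, 200)
        res = ArrivalTimingModel(days, years, cov, ("temp_Apr", "flow_Apr"), 2).fit(
            n_restarts=3, seed=0
        )
        grid = np.linspace(-200, 600, 20001)
        dens = res.pdf(grid, [9.0, 5.0])
        total = integrate.trapezoid(dens, grid)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestSelection:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(5)
        cov = _cov(rng.normal(9, 1.2, 12))
        days, years = _simulate(rng, 195.0, -1.36, 6.0, cov, 100)
        res, table = select_arrival_model(days, years, cov, 1,
                                          candidates=["temp_Apr"], seed=0)
        assert res.model.spec == ("temp_Apr",)
        assert len(table) == 1

    def test_identical_candidates_tie_break_by_order(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(9, 1.2, 12)
        cov = _cov(vals, extra={"temp_Apr_copy": vals})
        days, years = _simulate(rng, 195.0, -1.36, 6.0, cov, 100)
        res, table = select_arrival_model(
            days, years, cov, 1, candidates=["temp_Apr", "temp_Apr_copy"], seed=0
        )
        assert res.model.spec == ("temp_Apr",)

    def test_true_driver_selected_in_most_replicates(self):
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            temps = rng.normal(9.0, 1.2, 12)
            cov = _cov(temps, extra={
                "temp_May": rng.normal(13.0, 1.2, 12),
                "flow_Apr": rng.normal(5.0, 0.8, 12),
            })
            days, years = _simulate(rng, 195.0, -1.36, 6.0, cov, 150)
            res, _ = select_arrival_model(
                days, years, cov, 1,
                candidates=["temp_Apr", "temp_May", "flow_Apr"],
                n_restarts=2, seed=rep,
            )
            wins += res.model.spec == ("temp_Apr",)
        assert wins / n_rep >= 0.95


class TestSimulate:
    def _results(self, beta0, beta1, sigma, spec=("temp_Apr",)):
        d = {
            "n_components": len(spec),
            "spec": list(spec),
            "slope_identified": [True] * len(spec),
            "theta": list(beta0) + list(beta1) + [float(np.log(s)) for s in sigma],
            "loglik": 0.0,
            "cov": np.zeros((3 * len(spec), 3 * len(spec))).tolist(),
            "param_names": [], "nobs": 100,
        }
        if len(spec) == 2:
            d["theta"].append(0.0)  # p = 0.5
        return ArrivalTimingResults.from_dict(d)

    def test_tiny_sigma_concentrates_on_mean(self):
        res = self._results([180.0], [0.0], [1e-6])
        cov = pd.DataFrame({"temp_Apr": [9.0]}, index=[2010])
        sim = res.simulate(cov, 200, np.random.default_rng(0))
        assert (sim["day"] == 180).all()

    def test_sample_mean_matches_mu(self):
        res = self._results([180.0], [-2.0], [6.0])
        cov = pd.DataFrame({"temp_Apr": [10.0]}, index=[2010])
        n = 100_000
        sim = res.simulate(cov, n, np.random.default_rng(1))
        mu = 180.0 - 2.0 * 10.0
        assert sim["day"].mean() == pytest.approx(mu, abs=3 * 6.0 / np.sqrt(n) + 0.05)

    def test_covariate_unit_shift_moves_mean_by_slope(self):
        res = self._results([180.0], [-2.0], [4.0])
        cov = pd.DataFrame({"temp_Apr": [10.0, 11.0]}, index=[2010, 2011])
        n = 50_000
        m0 = res.simulate(cov, n, np.random.default_rng(2), years=[2010])["day"].mean()
        m1 = res.simulate(cov, n, np.random.default_rng(2), years=[2011])["day"].mean()
        assert m1 - m0 == pytest.approx(-2.0, abs=0.1)


class TestAdequacy:
    def test_qq_correlation_on_well_specified_data(self):
        rng = np.random.default_rng(8)
        cov = _cov(rng.normal(9, 1.2, 12))
        days, years = _simulate(rng, 195.0, -1.36, 6.0, cov, 500)
        res = ArrivalTimingModel(days, years, cov, ("temp_Apr",), 1).fit(seed=0)
        assert qq_correlation(res, days, years) >= 0.97


def test_annual_covariates_shapes(obs_env):
    cov = annual_covariates(obs_env["BON"])
    assert len(cov) == 12
    expected = {f"{v}_{m}" for v in ("temp", "flow")
                for m in ("Mar", "Apr", "May", "Jun",
                          "Mar_Apr", "Apr_May", "May_Jun")}
    assert expected == set(cov.columns)
    # bimonthly means lie between the two monthly means
    lo = np.minimum(cov["temp_Mar"], cov["temp_Apr"])
    hi = np.maximum(cov["temp_Mar"], cov["temp_Apr"])
    assert ((cov["temp_Mar_Apr"] >= lo - 1e-9) & (cov["temp_Mar_Apr"] <= hi + 1e-9)).all()
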