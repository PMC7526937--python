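"""Binomial penalized-spline survival models: fitting, selection, AUC, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from upmigrate.io import ValidationError
from upmigrate.survival import (
    ReachSurvivalModel,
    SeparationError,
    SurvivalPredictor,
    auc,
    dredge_select,
    prefilter_smooths,
)


def _design(n=2000, seed=0, beta_T=-0.3, beta_J=-0.8, year_sd=0.3,
            intercept=1.0, linear=True):
    """Binary outcomes from a logistic truth over (T, F, M, J, A, year)."""
    rng = np.random.default_rng(seed)
    T = rng.uniform(10, 24, n)
    F = rng.uniform(500, 3000, n)
    logM = rng.normal(4.8, 0.4, n)
    J = rng.random(n) < 0.4
    A = rng.choice(["1", "2", "3+"], n, p=[0.2, 0.6, 0.2])
    years = np.arange(2004, 2016)
    year = rng.choice(years, n)
    y_eff = dict(zip(years, rng.normal(0, year_sd, len(years))))
    t_term = beta_T * (T - 17.0) if linear else beta_T * np.maximum(T - 15, 0)
    eta = intercept + t_term + beta_J * J + np.array([y_eff[y] for y in year])
    S = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(
        {"T": T, "F": F, "logM": logM, "crootC": rng.uniform(2, 12, n),
         "population": "P1", "A": A,
         "J": np.where(J, "transported", "in_river"), "H": "hatchery",
         "year": year, "S": S}
    ), eta


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_predictions_give_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_toy_set_matches_pair_enumeration(self):
        pred = np.array([0.2, 0.7, 0.4, 0.4, 0.9, 0.1])
        obs = np.array([0, 1, 1, 0, 1, 0])
        pos, neg = pred[obs == 1], pred[obs == 0]
        total = 0.0
        for p in pos:
            for q in neg:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
        assert auc(pred, obs) == pytest.approx(total / (len(pos) * len(neg)))

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        pred = rng.random(500).round(2)  # induce ties
        obs = (rng.random(500) < pred).astype(int)
        assert auc(pred, obs) == pytest.approx(roc_auc_score(obs, pred))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.4], [1, 1])


class TestFit:
    def test_logistic_linear_truth_recovered(self):
        design, eta = _design(n=5000, seed=1, year_sd=0.2)
        res = ReachSurvivalModel(design, ("T",), ("J",)).fit()
        # fitted logit should track the truth tightly
        pred = res.predict(design)
        r = np.corrcoef(logit(np.clip(pred, 1e-9, 1 - 1e-9)), eta)[0, 1]
        assert r > 0.95
        # transport effect recovered
        coef = res.params()["J[transported]"]
        se = np.sqrt(res.cov[res.model.coef_names.index("J[transported]"),
                             res.model.coef_names.index("J[transported]")])
        assert abs(coef - (-0.8)) < 2.5 * se

    def test_unpenalized_factors_match_statsmodels_glm(self):
        import statsmodels.api as sm

        design, _ = _design(n=1500, seed=2)
        res = ReachSurvivalModel(design, (), ("J", "A"), include_year=False).fit()
        X = pd.get_dummies(design[["J", "A"]], drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
        glm = sm.GLM(design["S"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            np.sort(res.beta), np.sort(glm.params.to_numpy()), atol=1e-5
        )
        np.testing.assert_allclose(res.fittedvalues, glm.fittedvalues, atol=1e-6)

    def test_all_survived_raises_separation(self):
        design, _ = _design(n=200, seed=3)
        design["S"] = 1
        with pytest.raises(SeparationError):
            ReachSurvivalModel(design, ("T",), ())

    def test_perfectly_separable_covariate_raises(self):
        design, _ = _design(n=400, seed=4)
        design["S"] = (design["T"] > 17).astype(int)
        with pytest.raises(SeparationError):
            ReachSurvivalModel(design, ("T",), (), include_year=False).fit()

    def test_collinear_pair_rejected_naming_pair(self):
        design, _ = _design(n=500, seed=5)
        design["F"] = 100 * design["T"] + np.random.default_rng(0).normal(0, 1, 500)
        with pytest.raises(ValidationError, match="T and F"):
            ReachSurvivalModel(design, ("T", "F"), ())

    def test_reach_rules_enforced(self):
        design, _ = _design(n=300, seed=6)
        with pytest.raises(ValidationError, match="Columbia"):
            ReachSurvivalModel(design, ("C",), (), reach="Snake")
        with pytest.raises(ValidationError, match="Snake/Salmon"):
            ReachSurvivalModel(design, ("M",), (), reach="Columbia")
        with pytest.raises(ValidationError, match="sockeye"):
            ReachSurvivalModel(design, ("T",), ("P", "H"), species="sockeye")


class TestPredict:
    def test_intercept_only_balanced_data_predicts_half(self):
        rng = np.random.default_rng(7)
        design = pd.DataFrame(
            {"T": rng.uniform(10, 20, 400), "population": "P1",
             "year": 2010, "S": np.tile([0, 1], 200)}
        )
        res = ReachSurvivalModel(design, (), (), include_year=False).fit()
        np.testing.assert_allclose(res.predict(design), 0.5, atol=1e-8)

    def test_prediction_at_fitted_datum_equals_fitted_value(self):
        design, _ = _design(n=800, seed=8)
        res = ReachSurvivalModel(design, ("T", "F"), ("J",),
                                 include_year=False).fit()
        np.testing.assert_allclose(
            res.predict(design), res.fittedvalues, atol=1e-10
        )

    def test_year_effect_shifts_logit(self):
        design, _ = _design(n=800, seed=9)
        res = ReachSurvivalModel(design, ("T",), ()).fit()
        p0 = res.predict(design.iloc[:5], year_effect=0.0)
        p1 = res.predict(design.iloc[:5], year_effect=1.0)
        np.testing.assert_allclose(logit(p1) - logit(p0), 1.0, atol=1e-8)

    def test_unknown_factor_level_errors(self):
        design, _ = _design(n=400, seed=10)
        res = ReachSurvivalModel(design, (), ("J",)).fit()
        new = design.head(3).copy()
        new["J"] = "barge"
        with pytest.raises(ValidationError, match="barge"):
            res.predict(new)

    def test_hull_flag_matches_independent_convex_hull(self):
        from scipy.spatial import ConvexHull
        from matplotlib.path import Path as MplPath

        design, _ = _design(n=300, seed=11)
        res = ReachSurvivalModel(design, ("T",), ()).fit()
        rng = np.random.default_rng(0)
        query = pd.DataFrame(
            {"T": rng.uniform(5, 30, 200), "F": rng.uniform(0, 4000, 200)}
        )
        flags = res.outside_hull(query)
        pts = design[["T", "F"]].to_numpy()
        hull = ConvexHull(pts)
        poly = MplPath(pts[hull.vertices])
        inside = poly.contains_points(query[["T", "F"]].to_numpy(), radius=1e-9)
        agreement = np.mean(flags == ~inside)
        assert agreement > 0.99

    def test_predictor_round_trip_serialization(self):
        import json

        design, _ = _design(n=600, seed=12)
        res = ReachSurvivalModel(design, ("T", "F"), ("J", "A")).fit()
        pred = res.predictor()
        clone = SurvivalPredictor.from_dict(json.loads(json.dumps(pred.to_dict())))
        new = design.head(50)
        np.testing.assert_allclose(
            res.predict(new), clone.predict(new), atol=1e-12
        )
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        np.testing.assert_allclose(
            pred.draw_beta(rng1), clone.draw_beta(rng2), atol=1e-10
        )


class TestDredge:
    def test_single_term_candidate_space(self):
        design, _ = _design(n=1200, seed=13)
        best, table = dredge_select(design, ("T",), ())
        assert set(table["terms"]) == {"s(T) + y", "y", "null"}
        assert best.term_string() in {"s(T) + y", "y"}

    def test_null_model_in_ranking_and_aicc_ordering(self):
        design, _ = _design(n=1500, seed=14)
        best, table = dredge_select(design, ("T", "F"), ("J",))
        assert "null" in set(table["terms"])
        aicc_by_terms = table.set_index("terms")["AICc"]
        global_terms = "s(T) + s(F) + J + y"
        assert best.aicc <= aicc_by_terms[global_terms] + 1e-9
        assert best.aicc <= aicc_by_terms["null"] + 1e-9

    def test_simplest_within_two_aicc_selected(self):
        # strong s(T) and J effects, F pure noise: the extra-term models sit
        # within ~2 AICc but the selected model must be the smallest of them
        design, _ = _design(n=3000, seed=15)
        best, table = dredge_select(design, ("T", "F"), ("J",))
        cand = table[(table["dAICc"] < 2) & (table["terms"] != "null")]
        assert best.term_string() in set(cand["terms"])
        n_best = len(best.model.smooth_terms) + len(best.model.factor_terms)
        assert n_best == cand["n_terms"].min()


def test_prefilter_drops_collinear_later_term():
    rng = np.random.default_rng(16)
    n = 500
    T = rng.uniform(10, 20, n)
    design = pd.DataFrame(
        {"T": T, "F": 10 * T + rng.normal(0, 1, n),
         "logM": rng.normal(5, 0.5, n)}
    )
    kept, dropped = prefilter_smooths(design, ("T", "F", "M"))
    assert kept == ("T", "M")
    assert dropped == ("F",)
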