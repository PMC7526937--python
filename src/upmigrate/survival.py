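"""Binomial penalized-spline survival models per species and reach.

The reach survival state S_i (1 survived, 0 died) is modeled as

    S_i ~ s(T_i) + s(F_i) + s(C_i) or s(M_i) + P_i + A_i + J_i + H_i + y

with thin-plate-style penalized spline smooths (basis dimension 4 for T and
F, 3 for C and M), categorical factors, and a Gaussian random intercept for
migration year implemented as a ridge-penalized factor smooth.  Smoothing
parameters are chosen by Laplace-approximate restricted marginal likelihood
(REML, default) or GCV; all-subsets model selection uses AICc with the model
degrees of freedom taken as total effective df.

Reach-specific covariate rules: catch C enters only the Columbia reach,
cumulative thermal load M only the Snake and Salmon reaches; population and
origin are never used for sockeye (one population, nearly all hatchery).
Smooth covariates may only be combined when all pairwise |r| < 0.7.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.spatial import Delaunay, QhullError

from .io import ValidationError
from .smoothing import ThinPlateBasis

__all__ = [
    "DEFAULT_KNOTS",
    "ReachSurvivalModel",
    "ReachSurvivalResults",
    "SurvivalPredictor",
    "dredge_select",
    "auc",
    "SeparationError",
]

#: Basis dimensions: 4 for T and F; 3 for C and M (presumed unidirectional).
DEFAULT_KNOTS = {"T": 4, "F": 4, "C": 3, "M": 3}

#: Design-table column backing each model term (C and M enter transformed).
SMOOTH_COLUMN = {"T": "T", "F": "F", "C": "crootC", "M": "logM"}
FACTOR_COLUMN = {"P": "population", "A": "A", "J": "J", "H": "H"}

CORRELATION_LIMIT = 0.7


class SeparationError(RuntimeError):
    """Raised when the binomial fit exhibits (quasi-)complete separation."""


def auc(predicted, observed) -> float:
    """Mann-Whitney concordance: P(score_survivor > score_casualty), ties 1/2."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed)
    pos = predicted[observed == 1]
    neg = predicted[observed == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both survivors and casualties")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class _Block:
    """One design block: columns, penalty (None if unpenalized), metadata."""

    name: str
    X: np.ndarray
    penalty: np.ndarray | None = None
    rank: int = 0
    logdet_pos: float = 0.0
    labels: list = field(default_factory=list)


class ReachSurvivalModel:
    """Penalized binomial spline model of reach survival.

    Parameters
    ----------
    design : pd.DataFrame
        Design table (see :func:`upmigrate.covariates.build_design_table`)
        with outcome column ``S`` in {0, 1}.
    smooth_terms : sequence of str
        Subset of {"T", "F", "C", "M"}.
    factor_terms : sequence of str
        Subset of {"P", "A", "J", "H"}.
    species, reach : str, optional
        When given, the reach covariate rules are enforced.
    include_year : bool
        Include the ridge-penalized year random intercept (default True).
    """

    def __init__(
        self,
        design: pd.DataFrame,
        smooth_terms=("T", "F"),
        factor_terms=(),
        species: str | None = None,
        reach: str | None = None,
        knots: dict | None = None,
        include_year: bool = True,
        corr_limit: float = CORRELATION_LIMIT,
    ):
        self.design = design.reset_index(drop=True)
        self.smooth_terms = tuple(smooth_terms)
        self.factor_terms = tuple(factor_terms)
        self.species = species
        self.reach = reach
        self.include_year = include_year
        self.knots = dict(DEFAULT_KNOTS)
        if knots:
            self.knots.update(knots)
        self._check_rules()
        y = self.design["S"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("outcome S must be binary 0/1")
        if y.min() == y.max():
            raise SeparationError("all outcomes identical: survival not estimable")
        self.y = y.astype(float)
        self._check_correlation(corr_limit)
        self._build_blocks()

    # -- validation --------------------------------------------------------
    def _check_rules(self):
        if self.reach is not None:
            if "C" in self.smooth_terms and self.reach != "Columbia":
                raise ValidationError("catch (C) is a Columbia-reach covariate only")
            if "M" in self.smooth_terms and self.reach not in ("Snake", "Salmon"):
                raise ValidationError("cumulative temperature (M) applies to Snake/Salmon only")
        if self.species == "sockeye":
            bad = set(self.factor_terms) & {"P", "H"}
            if bad:
                raise ValidationError(f"terms {sorted(bad)} not used for sockeye")
        for t in self.smooth_terms:
            if t not in SMOOTH_COLUMN:
                raise ValidationError(f"unknown smooth term {t!r}")
        for t in self.factor_terms:
            if t not in FACTOR_COLUMN:
                raise ValidationError(f"unknown factor term {t!r}")

    def _check_correlation(self, limit):
        cols = [SMOOTH_COLUMN[t] for t in self.smooth_terms]
        for a, b in itertools.combinations(cols, 2):
            r = np.corrcoef(self.design[a], self.design[b])[0, 1]
            if abs(r) >= limit:
                raise ValidationError(
                    f"covariates {a} and {b} are collinear (|r| = {abs(r):.2f} >= {limit})"
                )

    # -- design assembly ---------------------------------------------------
    def _build_blocks(self):
        n = len(self.design)
        blocks = [_Block("intercept", np.ones((n, 1)), labels=["(Intercept)"])]
        self._bases = {}
        for t in self.smooth_terms:
            col = SMOOTH_COLUMN[t]
            basis = ThinPlateBasis(self.design[col].to_numpy(), self.knots[t])
            self._bases[t] = basis
            S = basis.penalty
            w = np.linalg.eigvalsh(S)
            pos = w[w > 1e-10 * max(w.max(), 1.0)]
            blocks.append(
                _Block(
                    f"s({t})", basis.transform(self.design[col].to_numpy()),
                    penalty=S, rank=basis.rank,
                    logdet_pos=float(np.sum(np.log(pos))),
                    labels=[f"s({t}).{i + 1}" for i in range(basis.n_coef)],
                )
            )
        self._factor_levels = {}
        for t in self.factor_terms:
            col = FACTOR_COLUMN[t]
            levels = sorted(self.design[col].astype(str).unique())
            if len(levels) < 2:
                raise ValidationError(f"factor {t} ({col}) has a single level")
            self._factor_levels[t] = levels
            X = np.column_stack(
                [(self.design[col].astype(str) == lv).to_numpy(float) for lv in levels[1:]]
            )
            blocks.append(
                _Block(t, X, labels=[f"{t}[{lv}]" for lv in levels[1:]])
            )
        if self.include_year:
            years = sorted(self.design["year"].unique())
            self._years = years
            X = np.column_stack(
                [(self.design["year"] == yv).to_numpy(float) for yv in years]
            )
            blocks.append(
                _Block(
                    "year", X, penalty=np.eye(len(years)), rank=len(years),
                    logdet_pos=0.0, labels=[f"year[{yv}]" for yv in years],
                )
            )
        else:
            self._years = []
        self.blocks = blocks
        self.X = np.hstack([b.X for b in blocks])
        self.coef_names = [lab for b in blocks for lab in b.labels]
        # Column slices per block.
        self._slices, start = {}, 0
        for b in blocks:
            self._slices[b.name] = slice(start, start + b.X.shape[1])
            start += b.X.shape[1]
        self.penalized = [b for b in blocks if b.penalty is not None]

    def _S_lambda(self, lam):
        p = self.X.shape[1]
        S = np.zeros((p, p))
        for b, l in zip(self.penalized, lam):
            sl = self._slices[b.name]
            S[sl, sl] += l * b.penalty
        return S

    # -- penalized IRLS ----------------------------------------------------
    def _pirls(self, S, beta0=None, maxiter=100, tol=1e-8):
        X, y = self.X, self.y
        n, p = X.shape
        if beta0 is None:
            mu = (y + 0.5) / 2.0
            eta = np.log(mu / (1 - mu))
            beta = None
        else:
            beta = beta0
            eta = X @ beta
        dev_pen_old = np.inf
        for _ in range(maxiter):
            mu = special.expit(eta)
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            XtW = X.T * w
            A = XtW @ X + S
            b = XtW @ z
            try:
                beta_new = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                A = A + 1e-8 * np.eye(p)
                beta_new = np.linalg.solve(A, b)
            eta = X @ beta_new
            mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
            dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
            dev_pen = dev + beta_new @ S @ beta_new
            beta = beta_new
            if abs(dev_pen_old - dev_pen) < tol * (abs(dev_pen) + 1.0):
                break
            dev_pen_old = dev_pen
        return beta, eta, dev

    def _criterion(self, log_lam, method, state):
        lam = np.exp(np.clip(log_lam, -25, 25))
        S = self._S_lambda(lam)
        beta, eta, dev = self._pirls(S, beta0=state.get("beta"))
        state["beta"] = beta
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        XtWX = (self.X.T * w) @ self.X
        H = XtWX + S
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e12
        edf = float(np.trace(np.linalg.solve(H, XtWX)))
        if method == "gcv":
            n = len(self.y)
            return n * dev / max(n - edf, 1e-3) ** 2
        # Laplace-approximate REML (phi = 1).
        loglik = -0.5 * dev
        pen = 0.5 * beta @ S @ beta
        logdetS = sum(
            b.rank * np.log(l) + b.logdet_pos
            for b, l in zip(self.penalized, lam)
        )
        lr = loglik - pen + 0.5 * logdetS - 0.5 * logdetH
        return -lr

    def fit(self, method: str = "reml", maxiter: int = 200) -> "ReachSurvivalResults":
        """Fit with smoothing parameters chosen by REML (or GCV).

        Raises :class:`SeparationError` when the fit exhibits complete
        separation (diverging coefficients / fitted probabilities at 0 or 1).
        """
        if method not in ("reml", "gcv"):
            raise ValueError("method must be 'reml' or 'gcv'")
        d = len(self.penalized)
        state = {}
        if d:
            res = optimize.minimize(
                self._criterion, np.zeros(d), args=(method, state),
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 0.05, "fatol": 1e-4},
            )
            log_lam = np.clip(res.x, -25, 25)
        else:
            log_lam = np.zeros(0)
        lam = np.exp(log_lam)
        S = self._S_lambda(lam)
        beta, eta, dev = self._pirls(S, beta0=state.get("beta"))
        if np.max(np.abs(eta)) > 30 or np.max(np.abs(beta)) > 1e4:
            raise SeparationError(
                "complete separation: fitted probabilities at 0/1 with "
                "diverging coefficients"
            )
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        XtWX = (self.X.T * w) @ self.X
        H = XtWX + S
        Vb = np.linalg.inv(H)
        Fmat = Vb @ XtWX
        edf = np.diag(Fmat)
        return ReachSurvivalResults(
            model=self, beta=beta, cov=Vb, lam=lam, deviance=float(dev),
            edf_by_coef=edf, fittedvalues=special.expit(eta),
        )


@dataclass
class ReachSurvivalResults:
    """Fitted reach survival model: coefficients, uncertainty, diagnostics."""

    model: ReachSurvivalModel
    beta: np.ndarray
    cov: np.ndarray
    lam: np.ndarray
    deviance: float
    edf_by_coef: np.ndarray
    fittedvalues: np.ndarray

    @property
    def nobs(self) -> int:
        return len(self.model.y)

    @property
    def edf(self) -> float:
        """Total effective degrees of freedom (model df for AICc)."""
        return float(np.sum(self.edf_by_coef))

    def edf_by_term(self) -> pd.Series:
        out = {}
        for b in self.model.blocks:
            sl = self.model._slices[b.name]
            out[b.name] = float(np.sum(self.edf_by_coef[sl]))
        return pd.Series(out)

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    @property
    def aicc(self) -> float:
        from .arrival import aicc as _aicc

        return _aicc(self.loglik, self.edf, self.nobs)

    @property
    def year_variance(self) -> float:
        """Random-intercept variance sigma_y^2 = phi / lambda_year."""
        for b, l in zip(self.model.penalized, self.lam):
            if b.name == "year":
                return float(1.0 / l)
        return 0.0

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.model.coef_names)

    # -- prediction --------------------------------------------------------
    def _design_matrix(self, data: pd.DataFrame, year_effect) -> np.ndarray:
        m = self.model
        n = len(data)
        cols = [np.ones((n, 1))]
        for t in m.smooth_terms:
            col = SMOOTH_COLUMN[t]
            cols.append(m._bases[t].transform(data[col].to_numpy(dtype=float)))
        for t in m.factor_terms:
            col = FACTOR_COLUMN[t]
            levels = m._factor_levels[t]
            vals = data[col].astype(str)
            unknown = sorted(set(vals) - set(levels))
            if unknown:
                raise ValidationError(f"unknown {t} level(s): {unknown}")
            cols.append(
                np.column_stack([(vals == lv).to_numpy(float) for lv in levels[1:]])
            )
        if m.include_year:
            cols.append(np.zeros((n, len(m._years))))
        return np.hstack(cols)

    def predict(self, data: pd.DataFrame, year_effect: float = 0.0,
                beta=None) -> np.ndarray:
        """Survival probability with the year random effect set to zero.

        ``year_effect`` (logit scale) is added to the linear predictor;
        ``beta`` substitutes a parameter draw for the point estimate.
        """
        X = self._design_matrix(data, year_effect)
        b = self.beta if beta is None else np.asarray(beta)
        return special.expit(X @ b + year_effect)

    def outside_hull(self, data: pd.DataFrame, vars=("T", "F")) -> np.ndarray:
        """Flag predictions outside the observed (T, F) convex hull.

        Mirrors plotting the observation envelope over prediction surfaces:
        survival estimates beyond the observed covariate hull are
        extrapolations.
        """
        obs = self.model.design[list(vars)].to_numpy(dtype=float)
        new = data[list(vars)].to_numpy(dtype=float)
        try:
            tri = Delaunay(obs)
        except QhullError:
            return np.ones(len(new), dtype=bool)
        return tri.find_simplex(new) < 0

    def auc(self) -> float:
        return auc(self.fittedvalues, self.model.y)

    def draw_beta(self, rng, repair: bool = True) -> np.ndarray:
        """One multivariate-normal coefficient draw (parameter uncertainty)."""
        cov = (self.cov + self.cov.T) / 2.0
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-8 * max(abs(w.max()), 1.0):
            if not repair:
                raise ValueError("coefficient covariance is not PSD")
            ww, V = np.linalg.eigh(cov)
            cov = V @ np.diag(np.clip(ww, 0.0, None)) @ V.T
        return rng.multivariate_normal(self.beta, cov, method="eigh")

    @property
    def baseline_population(self) -> str:
        """Most common population in the fitting data (prediction baseline)."""
        return str(self.model.design["population"].mode().iat[0])

    def predictor(self) -> "SurvivalPredictor":
        """A lightweight serializable predictor (no fitting data attached)."""
        m = self.model
        obs = m.design[["T", "F"]].to_numpy(dtype=float)
        return SurvivalPredictor(
            species=m.species, reach=m.reach,
            smooth_terms=m.smooth_terms, factor_terms=m.factor_terms,
            bases={t: m._bases[t] for t in m.smooth_terms},
            factor_levels=dict(m._factor_levels),
            n_year_cols=len(m._years),
            beta=self.beta.copy(), cov=self.cov.copy(),
            coef_names=list(m.coef_names),
            baseline_population=self.baseline_population,
            hull_points=obs,
        )

    def term_string(self) -> str:
        parts = [f"s({t})" for t in self.model.smooth_terms]
        parts += list(self.model.factor_terms)
        if self.model.include_year:
            parts.append("y")
        return " + ".join(parts) if parts else "null"

    def plot_term(self, term: str, n_points: int = 100, ax=None):
        """Partial-effect curve for one smooth term (probability scale).

        Other covariates are held at their median (continuous) or most
        common (factor) value, the year effect at zero.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        col = SMOOTH_COLUMN[term]
        grid = np.linspace(m.design[col].min(), m.design[col].max(), n_points)
        new = {}
        for t in m.smooth_terms:
            c = SMOOTH_COLUMN[t]
            new[c] = np.full(n_points, float(m.design[c].median()))
        new[col] = grid
        for t in m.factor_terms:
            c = FACTOR_COLUMN[t]
            new[c] = [m.design[c].mode().iat[0]] * n_points
        p = self.predict(pd.DataFrame(new))
        ax.plot(grid, p)
        ax.set_xlabel(col)
        ax.set_ylabel("predicted survival")
        ax.set_title(f"s({term}), edf = {self.edf_by_term()[f's({term})']:.2f}")
        return ax

    def summary(self) -> str:
        lines = [
            f"Reach survival model: S ~ {self.term_string()}"
            + (f"  [{self.model.species}/{self.model.reach}]"
               if self.model.species else ""),
            f"n = {self.nobs}, deviance = {self.deviance:.2f}, "
            f"edf = {self.edf:.2f}, AICc = {self.aicc:.2f}, AUC = {self.auc():.3f}",
            "effective df by term:",
            self.edf_by_term().to_string(float_format=lambda v: f"{v:.2f}"),
        ]
        if self.model.include_year:
            lines.append(f"year random-intercept variance: {self.year_variance:.4f}")
        return "\n".join(lines)


def prefilter_smooths(design: pd.DataFrame, smooth_terms, limit: float = CORRELATION_LIMIT):
    """Collinearity prefilter for a global term set.

    Greedily keeps smooth terms in the given priority order, dropping any
    whose backing covariate has |r| >= ``limit`` with an already-kept one.
    Returns ``(kept, dropped)``.
    """
    kept, dropped = [], []
    for t in smooth_terms:
        col = SMOOTH_COLUMN[t]
        ok = True
        for k in kept:
            r = np.corrcoef(design[col], design[SMOOTH_COLUMN[k]])[0, 1]
            if abs(r) >= limit:
                ok = False
                break
        (kept if ok else dropped).append(t)
    return tuple(kept), tuple(dropped)


@dataclass
class SurvivalPredictor:
    """Serializable fitted survival surface: predict + parameter draws.

    Carries everything projection needs — bases, factor levels, coefficient
    vector and covariance, the baseline population, and the observed (T, F)
    points for extrapolation flagging — without the fitting data.
    """

    species: str | None
    reach: str | None
    smooth_terms: tuple
    factor_terms: tuple
    bases: dict
    factor_levels: dict
    n_year_cols: int
    beta: np.ndarray
    cov: np.ndarray
    coef_names: list
    baseline_population: str
    hull_points: np.ndarray

    def _design_matrix(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        cols = [np.ones((n, 1))]
        for t in self.smooth_terms:
            col = SMOOTH_COLUMN[t]
            cols.append(self.bases[t].transform(data[col].to_numpy(dtype=float)))
        for t in self.factor_terms:
            col = FACTOR_COLUMN[t]
            levels = self.factor_levels[t]
            vals = data[col].astype(str)
            unknown = sorted(set(vals) - set(levels))
            if unknown:
                raise ValidationError(f"unknown {t} level(s): {unknown}")
            cols.append(
                np.column_stack([(vals == lv).to_numpy(float) for lv in levels[1:]])
            )
        if self.n_year_cols:
            cols.append(np.zeros((n, self.n_year_cols)))
        return np.hstack(cols)

    def predict(self, data: pd.DataFrame, year_effect: float = 0.0,
                beta=None) -> np.ndarray:
        X = self._design_matrix(data)
        b = self.beta if beta is None else np.asarray(beta)
        return special.expit(X @ b + year_effect)

    def draw_beta(self, rng, repair: bool = True) -> np.ndarray:
        cov = (self.cov + self.cov.T) / 2.0
        w, V = np.linalg.eigh(cov)
        if w.min() < -1e-8 * max(abs(w.max()), 1.0) and not repair:
            raise ValueError("coefficient covariance is not PSD")
        cov = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
        return rng.multivariate_normal(self.beta, cov, method="eigh")

    def outside_hull(self, data: pd.DataFrame, vars=("T", "F")) -> np.ndarray:
        new = data[list(vars)].to_numpy(dtype=float)
        try:
            tri = Delaunay(self.hull_points)
        except QhullError:
            return np.ones(len(new), dtype=bool)
        return tri.find_simplex(new) < 0

    def to_dict(self) -> dict:
        return {
            "species": self.species, "reach": self.reach,
            "smooth_terms": list(self.smooth_terms),
            "factor_terms": list(self.factor_terms),
            "bases": {t: b.to_dict() for t, b in self.bases.items()},
            "factor_levels": self.factor_levels,
            "n_year_cols": self.n_year_cols,
            "beta": self.beta.tolist(), "cov": self.cov.tolist(),
            "coef_names": self.coef_names,
            "baseline_population": self.baseline_population,
            "hull_points": self.hull_points.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalPredictor":
        return cls(
            species=d["species"], reach=d["reach"],
            smooth_terms=tuple(d["smooth_terms"]),
            factor_terms=tuple(d["factor_terms"]),
            bases={t: ThinPlateBasis.from_dict(b) for t, b in d["bases"].items()},
            factor_levels=d["factor_levels"],
            n_year_cols=int(d["n_year_cols"]),
            beta=np.asarray(d["beta"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            coef_names=list(d["coef_names"]),
            baseline_population=d["baseline_population"],
            hull_points=np.asarray(d["hull_points"], dtype=float),
        )


def dredge_select(
    design: pd.DataFrame,
    smooth_terms=("T", "F"),
    factor_terms=(),
    species: str | None = None,
    reach: str | None = None,
    method: str = "reml",
    delta_threshold: float = 2.0,
    knots: dict | None = None,
):
    """All-subsets AICc selection over the global term set.

    Every subset of the global smooth and factor terms is fitted (smooths
    enter or leave whole; the year random intercept is always included) and
    ranked by AICc with model df = total effective df.  Among models within
    ``delta_threshold`` AICc of the best, the selected model is the one with
    fewest terms (ties: fewest edf, then lexicographic term order).  The
    intercept-only null model is included in the ranking for reference.

    Returns ``(best_results, ranking_table)``.
    """
    terms = [("s", t) for t in smooth_terms] + [("f", t) for t in factor_terms]
    rows, fits = [], {}

    def _fit(subset_s, subset_f, include_year, label=None):
        try:
            res = ReachSurvivalModel(
                design, subset_s, subset_f, species=species, reach=reach,
                knots=knots, include_year=include_year,
            ).fit(method=method)
        except (ValidationError, SeparationError, np.linalg.LinAlgError) as exc:
            rows.append({"terms": label or "?", "n_terms": len(subset_s) + len(subset_f),
                         "df": np.nan, "AICc": np.inf, "AUC": np.nan,
                         "error": str(exc)})
            return
        label = label or res.term_string()
        rows.append({"terms": label, "n_terms": len(subset_s) + len(subset_f),
                     "df": res.edf, "AICc": res.aicc, "AUC": res.auc()})
        fits[label] = res

    for mask in itertools.product([False, True], repeat=len(terms)):
        subset = [t for t, keep in zip(terms, mask) if keep]
        ss = tuple(t for kind, t in subset if kind == "s")
        sf = tuple(t for kind, t in subset if kind == "f")
        _fit(ss, sf, include_year=True)
    _fit((), (), include_year=False, label="null")

    table = pd.DataFrame(rows)
    ranked = table[np.isfinite(table["AICc"])]
    if ranked.empty or not fits:
        raise RuntimeError("no survival model subset converged")
    table = table.sort_values("AICc", kind="stable").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].iloc[0]
    # Selection among subsets (never the year-free reference null row).
    cand = table[(table["dAICc"] < delta_threshold) & (table["terms"] != "null")]
    cand = cand.sort_values(
        ["n_terms", "df", "terms"], kind="stable"
    )
    best = fits[cand.iloc[0]["terms"]]
    return best, table
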