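"""Arrival-day phenology models at the first dam encountered (Bonneville).

Sockeye arrival day-of-year is modeled as a single Gaussian whose mean is a
linear function of an annual environmental metric; spring/summer Chinook as
a two-component Gaussian mixture in which each component mean tracks its own
annual metric:

    Pr(x | theta) = sum_k w_k Normal(x; mu_{k,t}, sigma_k),
    mu_{k,t} = beta0_k + beta1_k * E_{k,t}

with component standard deviations constant over years and the mixing weight
p (proportion spring-run) pooled across years.  Candidate metrics are the
monthly and bimonthly means of temperature and flow at Bonneville during
March-June; candidate models are compared by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "aicc",
    "annual_covariates",
    "ArrivalTimingModel",
    "ArrivalTimingResults",
    "select_arrival_model",
    "qq_correlation",
]

_MONTHS = {"Mar": 3, "Apr": 4, "May": 5, "Jun": 6}
_BIMONTHS = {"Mar_Apr": (3, 4), "Apr_May": (4, 5), "May_Jun": (5, 6)}


def aicc(loglik: float, k_params: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); requires n > k+1.
    """
    if n <= k_params + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k_params + 1}")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


def annual_covariates(env, flow_units: float = 1000.0) -> pd.DataFrame:
    """Monthly and bimonthly March-June means of temperature and flow, by year.

    ``env`` is the first-dam :class:`~upmigrate.io.EnvSeries`.  Flow metrics
    are reported in units of ``flow_units`` m3/s (default 1000 m3/s) so that
    slope coefficients are on a convenient scale.  Returns a DataFrame
    indexed by year with columns like ``temp_Apr`` and ``flow_Apr_May``.
    """
    df = env.data.copy()
    df["year"] = df.index.year
    df["month"] = df.index.month
    rows = {}
    for year, sub in df.groupby("year"):
        row = {}
        ok = True
        for name, months in list(_MONTHS.items()) + list(_BIMONTHS.items()):
            months = (months,) if isinstance(months, int) else months
            chunk = sub[sub["month"].isin(months)]
            # require full coverage of the window
            n_days = sum(
                pd.Timestamp(year=year, month=m, day=1).days_in_month for m in months
            )
            if len(chunk) < n_days or chunk[["temperature", "flow"]].isna().any().any():
                ok = False
                continue
            row[f"temp_{name}"] = chunk["temperature"].mean()
            row[f"flow_{name}"] = chunk["flow"].mean() / flow_units
        if ok:
            rows[year] = row
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "year"
    return out


def _softplus_inv(x):
    return np.log(np.expm1(x))


@dataclass
class ArrivalTimingModel:
    """Maximum-likelihood arrival-day model.

    Parameters
    ----------
    day : array-like
        Arrival day-of-year per fish (real-valued permitted).
    year : array-like
        Migration year per fish.
    covariates : pd.DataFrame
        Annual metrics indexed by year (see :func:`annual_covariates`).
    spec : tuple of str
        One metric name per component (length ``n_components``).
    n_components : int
        1 (sockeye-style) or 2 (Chinook-style spring/summer mixture).
    """

    day: np.ndarray
    year: np.ndarray
    covariates: pd.DataFrame
    spec: tuple
    n_components: int = 1

    def __post_init__(self):
        self.day = np.asarray(self.day, dtype=float)
        self.year = np.asarray(self.year, dtype=int)
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if len(self.spec) != self.n_components:
            raise ValueError("spec must name one covariate per component")
        years = np.unique(self.year)
        missing = [y for y in years if y not in self.covariates.index]
        if missing:
            raise ValueError(f"covariates missing for years {missing}")
        # Per-fish covariate values for each component.
        self._E = np.column_stack(
            [self.covariates.loc[self.year, m].to_numpy(dtype=float) for m in self.spec]
        )
        # Identifiability of the slope requires the metric to vary.
        self.slope_identified = [
            bool(np.ptp(self.covariates.loc[years, m].to_numpy()) > 1e-12)
            for m in self.spec
        ]

    # -- likelihood --------------------------------------------------------
    def _unpack(self, theta):
        k = self.n_components
        b0 = theta[0:k]
        b1 = np.where(self.slope_identified, theta[k:2 * k], 0.0)
        sigma = np.exp(theta[2 * k:3 * k])
        if k == 2:
            p = 1.0 / (1.0 + np.exp(-theta[-1]))
            w = np.array([p, 1.0 - p])
        else:
            w = np.array([1.0])
        return b0, b1, sigma, w

    def loglike(self, theta) -> float:
        b0, b1, sigma, w = self._unpack(theta)
        mu = b0[None, :] + b1[None, :] * self._E  # n x k
        z = (self.day[:, None] - mu) / sigma[None, :]
        logcomp = (
            np.log(w)[None, :] - 0.5 * z * z - np.log(sigma)[None, :]
            - 0.5 * np.log(2 * np.pi)
        )
        m = logcomp.max(axis=1)
        return float(np.sum(m + np.log(np.exp(logcomp - m[:, None]).sum(axis=1))))

    def _initial_thetas(self, rng, n_restarts):
        k = self.n_components
        x = self.day
        inits = []
        if k == 1:
            base = np.array([x.mean(), 0.0, np.log(max(x.std(), 1.0))])
        else:
            med = np.median(x)
            lo, hi = x[x <= med], x[x > med]
            base = np.array(
                [
                    lo.mean(), hi.mean(), 0.0, 0.0,
                    np.log(max(lo.std(), 1.0)), np.log(max(hi.std(), 1.0)),
                    0.0,
                ]
            )
            base = base[[0, 1, 2, 3, 4, 5, 6]]
        # reorder into [b0..., b1..., logsigma..., (logitp)]
        if k == 1:
            thetas = [base]
        else:
            thetas = [np.concatenate([base[:2], base[2:4], base[4:6], base[6:]])]
        for _ in range(n_restarts - 1):
            t = thetas[0].copy()
            t[0:k] += rng.normal(0, 5, size=k)
            t[k:2 * k] += rng.normal(0, 0.5, size=k)
            t[2 * k:3 * k] += rng.normal(0, 0.3, size=k)
            if k == 2:
                t[-1] += rng.normal(0, 0.7)
            thetas.append(t)
        return thetas

    def fit(self, n_restarts: int = 10, seed: int = 0) -> "ArrivalTimingResults":
        """Fit by direct maximum likelihood with random restarts.

        Optimizes on a transformed scale (log sigma, logit p) by BFGS; the
        best of ``n_restarts`` starts is kept.  Raises on non-convergence of
        every start or on a degenerate (sigma -> 0) solution.
        """
        rng = np.random.default_rng(seed)
        best, failures = None, []
        for theta0 in self._initial_thetas(rng, n_restarts):
            res = optimize.minimize(
                lambda t: -self.loglike(t), theta0, method="BFGS",
                options={"maxiter": 500},
            )
            if not np.isfinite(res.fun):
                failures.append(str(res.message))
                continue
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if best is None:
            raise RuntimeError(f"arrival model did not converge: {failures}")
        theta = best.x
        k = self.n_components
        sigma = np.exp(theta[2 * k:3 * k])
        if np.any(sigma < 1e-3):
            raise RuntimeError("degenerate fit: component standard deviation -> 0")
        # Order components so the earlier (smaller mean arrival) component is
        # first and labeled spring.  Each component is tied to its own
        # metric, so a swap also swaps the covariate spec.
        model = self
        if k == 2:
            b0, b1, sig, w = self._unpack(theta)
            mean_mu = b0 + b1 * self._E.mean(axis=0)
            if mean_mu[0] > mean_mu[1]:
                model = ArrivalTimingModel(
                    self.day, self.year, self.covariates,
                    (self.spec[1], self.spec[0]), 2,
                )
                theta = np.concatenate(
                    [theta[[1, 0]], theta[[3, 2]], theta[[5, 4]], [-theta[-1]]]
                )
        loglik = model.loglike(theta)
        cov, names = model._covariance(theta)
        return ArrivalTimingResults(model=model, theta=theta, loglik=loglik,
                                    cov=cov, param_names=names)

    # -- uncertainty -------------------------------------------------------
    def _natural(self, theta):
        b0, b1, sigma, w = self._unpack(theta)
        if self.n_components == 2:
            return np.concatenate([b0, b1, sigma, [w[0]]])
        return np.concatenate([b0, b1, sigma])

    def _covariance(self, theta):
        """Observed-information covariance on the natural parameter scale."""
        k = self.n_components
        names = (
            [f"beta0_{i + 1}" for i in range(k)]
            + [f"beta1_{i + 1}" for i in range(k)]
            + [f"sigma_{i + 1}" for i in range(k)]
        )
        if k == 2:
            names.append("p_spring")

        def nll_nat(eta):
            b0 = eta[0:k]
            b1 = eta[k:2 * k]
            sigma = eta[2 * k:3 * k]
            t = np.concatenate([b0, b1, np.log(np.maximum(sigma, 1e-8))])
            if k == 2:
                p = np.clip(eta[-1], 1e-8, 1 - 1e-8)
                t = np.concatenate([t, [np.log(p / (1 - p))]])
            return -self.loglike(t)

        eta0 = self._natural(theta)
        n_par = len(eta0)
        H = np.zeros((n_par, n_par))
        h = 1e-4 * np.maximum(np.abs(eta0), 1.0)
        for i in range(n_par):
            for j in range(i, n_par):
                ei = np.zeros(n_par); ei[i] = h[i]
                ej = np.zeros(n_par); ej[j] = h[j]
                fpp = nll_nat(eta0 + ei + ej)
                fpm = nll_nat(eta0 + ei - ej)
                fmp = nll_nat(eta0 - ei + ej)
                fmm = nll_nat(eta0 - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        # Unidentified slopes: excise before inversion, report NaN rows.
        free = np.ones(n_par, dtype=bool)
        for i, ok in enumerate(self.slope_identified):
            if not ok:
                free[k + i] = False
        cov = np.full((n_par, n_par), np.nan)
        try:
            sub = np.linalg.inv(H[np.ix_(free, free)])
            cov[np.ix_(free, free)] = sub
        except np.linalg.LinAlgError:
            pass
        return cov, names


@dataclass
class ArrivalTimingResults:
    """Fitted arrival model: estimates, covariance, AICc, simulation."""

    model: ArrivalTimingModel
    theta: np.ndarray
    loglik: float
    cov: np.ndarray
    param_names: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.model.n_components

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.model._natural(self.theta), index=self.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.param_names)

    @property
    def k_params(self) -> int:
        k = self.n_components
        n_par = 3 * k + (1 if k == 2 else 0)
        return n_par - sum(not ok for ok in self.model.slope_identified)

    @property
    def nobs(self) -> int:
        return len(self.model.day)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k_params, self.nobs)

    @property
    def weights(self) -> np.ndarray:
        return self.model._unpack(self.theta)[3]

    def component_params(self) -> pd.DataFrame:
        b0, b1, sigma, w = self.model._unpack(self.theta)
        labels = ["spring", "summer"] if self.n_components == 2 else ["single"]
        return pd.DataFrame(
            {"component": labels, "metric": list(self.model.spec),
             "beta0": b0, "beta1": b1, "sigma": sigma, "weight": w}
        )

    def component_means(self, covariate_values) -> np.ndarray:
        """mu_k for given metric values (array-like, one per component)."""
        b0, b1, _, _ = self.model._unpack(self.theta)
        return b0 + b1 * np.asarray(covariate_values, dtype=float)

    def _year_values(self, covariates: pd.DataFrame, year) -> np.ndarray:
        return np.array(
            [covariates.loc[year, m] for m in self.model.spec], dtype=float
        )

    def pdf(self, x, covariate_values) -> np.ndarray:
        b0, b1, sigma, w = self.model._unpack(self.theta)
        mu = self.component_means(covariate_values)
        x = np.asarray(x, dtype=float)
        return np.sum(
            [w[k] * stats.norm.pdf(x, mu[k], sigma[k]) for k in range(len(w))],
            axis=0,
        )

    def cdf(self, x, covariate_values) -> np.ndarray:
        b0, b1, sigma, w = self.model._unpack(self.theta)
        mu = self.component_means(covariate_values)
        x = np.asarray(x, dtype=float)
        return np.sum(
            [w[k] * stats.norm.cdf(x, mu[k], sigma[k]) for k in range(len(w))],
            axis=0,
        )

    def simulate(self, covariates: pd.DataFrame, n_fish: int, rng,
                 years=None) -> pd.DataFrame:
        """Draw arrival days for ``n_fish`` per year.

        Component is drawn Bernoulli(p); day is drawn from the component
        normal and rounded to integer day-of-year.  Returns a DataFrame with
        columns year, day, component.
        """
        b0, b1, sigma, w = self.model._unpack(self.theta)
        labels = ["spring", "summer"] if self.n_components == 2 else ["single"]
        if years is None:
            years = covariates.index
        frames = []
        for y in years:
            mu = self.component_means(self._year_values(covariates, y))
            comp = rng.choice(len(w), size=n_fish, p=w / w.sum())
            day = rng.normal(mu[comp], sigma[comp])
            frames.append(
                pd.DataFrame(
                    {"year": y, "day": np.rint(day).astype(int),
                     "component": [labels[c] for c in comp]}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def predicted_quantiles(self, covariates: pd.DataFrame, years, qs) -> np.ndarray:
        """Quantiles of the pooled (across years) predicted arrival distribution."""
        years = list(years)
        grid = np.linspace(0.0, 400.0, 8001)
        cdf = np.mean(
            [self.cdf(grid, self._year_values(covariates, y)) for y in years],
            axis=0,
        )
        return np.interp(np.asarray(qs, dtype=float), cdf, grid)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "spec": list(self.model.spec),
            "slope_identified": list(map(bool, self.model.slope_identified)),
            "theta": self.theta.tolist(),
            "loglik": float(self.loglik),
            "cov": np.asarray(self.cov, dtype=float).tolist(),
            "param_names": list(self.param_names),
            "nobs": self.nobs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrivalTimingResults":
        """Rebuild a predictor-only results object (no fitting data)."""
        model = ArrivalTimingModel.__new__(ArrivalTimingModel)
        model.n_components = int(d["n_components"])
        model.spec = tuple(d["spec"])
        model.slope_identified = list(d["slope_identified"])
        model.day = np.zeros(int(d.get("nobs", 0)))
        model.year = np.zeros(int(d.get("nobs", 0)), dtype=int)
        model.covariates = pd.DataFrame()
        return cls(
            model=model, theta=np.asarray(d["theta"], dtype=float),
            loglik=float(d["loglik"]),
            cov=np.asarray(d["cov"], dtype=float),
            param_names=list(d["param_names"]),
        )

    def plot_density(self, covariate_values, observed_days=None, ax=None):
        """Predicted arrival-day density for one year's metric values,
        optionally over a histogram of observed days."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(60, 330, 541)
        if observed_days is not None:
            ax.hist(observed_days, bins=40, density=True, alpha=0.4,
                    label="observed")
        ax.plot(grid, self.pdf(grid, covariate_values), label="model")
        ax.set_xlabel("day of year")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def summary(self) -> str:
        tab = self.component_params()
        lines = [
            "Arrival timing model"
            f" ({self.n_components}-component Gaussian{' mixture' if self.n_components > 1 else ''})",
            f"n = {self.nobs}, years = {len(np.unique(self.model.year))}, "
            f"loglik = {self.loglik:.2f}, k = {self.k_params}, AICc = {self.aicc:.2f}",
            tab.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        se = self.bse
        lines.append(
            "standard errors: "
            + ", ".join(f"{n}={se[n]:.4f}" for n in self.param_names)
        )
        if not all(self.model.slope_identified):
            bad = [m for m, ok in zip(self.model.spec, self.model.slope_identified) if not ok]
            lines.append(f"WARNING: slope unidentifiable (no covariate variation): {bad}")
        return "\n".join(lines)


def select_arrival_model(
    day,
    year,
    covariates: pd.DataFrame,
    n_components: int = 1,
    candidates=None,
    n_restarts: int = 4,
    seed: int = 0,
) -> tuple[ArrivalTimingResults, pd.DataFrame]:
    """All-combinations AICc selection over candidate annual metrics.

    For a single component every candidate metric is tried; for two
    components every ordered pair (one metric per component).  Returns the
    lowest-AICc fit and the full ranking table; ties break deterministically
    by candidate order.
    """
    if candidates is None:
        candidates = list(covariates.columns)
    if n_components == 1:
        specs = [(m,) for m in candidates]
    else:
        specs = [(a, b) for a in candidates for b in candidates]
    rows, fits = [], {}
    for i, spec in enumerate(specs):
        try:
            res = ArrivalTimingModel(
                day, year, covariates, spec, n_components
            ).fit(n_restarts=n_restarts, seed=seed)
            rows.append({"rank_order": i, "spec": spec, "loglik": res.loglik,
                         "k": res.k_params, "AICc": res.aicc})
            fits[spec] = res
        except (RuntimeError, ValueError) as exc:
            rows.append({"rank_order": i, "spec": spec, "loglik": np.nan,
                         "k": np.nan, "AICc": np.inf, "error": str(exc)})
    table = pd.DataFrame(rows)
    if not np.isfinite(table["AICc"]).any():
        raise RuntimeError("no candidate arrival model converged")
    table = table.sort_values(["AICc", "rank_order"], kind="stable").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].iloc[0]
    best_spec = table.iloc[0]["spec"]
    return fits[best_spec], table


def qq_correlation(results: ArrivalTimingResults, day, year,
                   percentiles=None) -> float:
    """Pearson correlation of predicted vs observed arrival-day quantiles.

    Quantiles are the 1st-99th percentiles of the pooled distribution across
    all years in the data.
    """
    if percentiles is None:
        percentiles = np.arange(1, 100)
    day = np.asarray(day, dtype=float)
    years = np.unique(np.asarray(year))
    obs_q = np.percentile(day, percentiles)
    pred_q = results.predicted_quantiles(
        results.model.covariates, years, np.asarray(percentiles) / 100.0
    )
    return float(np.corrcoef(obs_q, pred_q)[0, 1])
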