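"""Low-rank thin-plate-style penalized spline bases (1-D).

The smooth f(x) is represented as a radial thin-plate basis on ``dim`` knots
placed at quantiles of the data,

    f(x) = a0 + a1 x + sum_j delta_j |x - kappa_j|^3,

subject to the natural constraints sum_j delta_j = 0 and
sum_j delta_j kappa_j = 0, with wiggliness penalty delta' E delta where
E_jl = |kappa_j - kappa_l|^3.  The constraints are absorbed by a null-space
reparameterization, and the constant is removed (sum-to-zero identifiability
via column centering) so the smooth contributes ``dim - 1`` coefficients:
one unpenalized linear term plus ``dim - 2`` penalized ones.  The penalty is
positive semidefinite with null space exactly the linear functions.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["ThinPlateBasis"]


def _kernel(r):
    return np.abs(r) ** 3


class ThinPlateBasis:
    """Thin-plate-style penalized spline basis fit to training data.

    Parameters
    ----------
    x : array-like
        Training covariate values (the knots are placed at quantiles of the
        distinct values).
    dim : int
        Basis dimension (mgcv's ``k``): number of coefficients before the
        sum-to-zero constraint.  Must be >= 3 and <= number of distinct x.
    """

    def __init__(self, x, dim: int):
        x = np.asarray(x, dtype=float)
        ux = np.unique(x)
        if dim < 3:
            raise ValueError("basis dimension must be >= 3")
        if len(ux) < dim:
            raise ValueError(
                f"need >= {dim} distinct covariate values, got {len(ux)}"
            )
        self.dim = int(dim)
        # Knots at quantiles of the distinct values (mgcv-like placement).
        probs = np.linspace(0, 1, dim)
        self.knots = np.quantile(ux, probs)
        # Jitter exact duplicates (possible with heavily tied quantiles).
        for i in range(1, dim):
            if self.knots[i] <= self.knots[i - 1]:
                self.knots[i] = self.knots[i - 1] + 1e-8 * max(1.0, abs(self.knots[i - 1]))
        K = self.knots
        E = _kernel(K[:, None] - K[None, :])
        T = np.column_stack([np.ones(dim), K])
        # Z spans the null space of T' (constraint T' delta = 0).
        q, _ = linalg.qr(T)
        Z = q[:, 2:]                      # dim x (dim-2)
        self._Z = Z
        S = Z.T @ E @ Z                   # penalty for the radial coefficients
        S = (S + S.T) / 2.0
        # Guard: clip tiny negative eigenvalues from roundoff.
        w, V = np.linalg.eigh(S)
        w = np.clip(w, 0.0, None)
        S = V @ np.diag(w) @ V.T
        # Column means for the sum-to-zero (centering) constraint.
        raw = self._raw(x)
        self._means = raw.mean(axis=0)
        # Scale columns to unit RMS for numerical balance; the penalty is
        # rescaled to match so the fitted smooth is unchanged.
        self._scales = np.maximum(raw.std(axis=0), 1e-12)
        Dinv = np.diag(1.0 / self._scales[1:])
        self.penalty_radial = Dinv @ S @ Dinv
        self.rank = dim - 2

    def _raw(self, x):
        """Uncentered columns: [x, radial part (constrained)]."""
        x = np.asarray(x, dtype=float)
        R = _kernel(x[:, None] - self.knots[None, :]) @ self._Z
        return np.column_stack([x, R])

    def transform(self, x) -> np.ndarray:
        """Design columns for ``x``: (n, dim-1), centered on the training data."""
        raw = (self._raw(x) - self._means) / self._scales
        return raw

    @property
    def n_coef(self) -> int:
        return self.dim - 1

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "knots": self.knots.tolist(),
            "Z": self._Z.tolist(),
            "means": self._means.tolist(),
            "scales": self._scales.tolist(),
            "penalty_radial": self.penalty_radial.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThinPlateBasis":
        obj = cls.__new__(cls)
        obj.dim = int(d["dim"])
        obj.knots = np.asarray(d["knots"], dtype=float)
        obj._Z = np.asarray(d["Z"], dtype=float)
        obj._means = np.asarray(d["means"], dtype=float)
        obj._scales = np.asarray(d["scales"], dtype=float)
        obj.penalty_radial = np.asarray(d["penalty_radial"], dtype=float)
        obj.rank = obj.dim - 2
        return obj

    @property
    def penalty(self) -> np.ndarray:
        """(dim-1, dim-1) PSD penalty; zero row/col for the linear term."""
        S = np.zeros((self.n_coef, self.n_coef))
        S[1:, 1:] = self.penalty_radial
        return S
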