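"""Closed-form polynomial regression of depth on peak Doppler frequency.

Faster, deeper compressions produce higher peak Doppler; a second-order
polynomial maps a cycle's maximum Doppler frequency (Hz) to its depth (cm).
The fit solves the least-squares normal equations ``X'X w = X'y``; the
feature is z-scored before polynomial expansion for conditioning, and
coefficients are reported in both bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial


@dataclass
class PolyRegressionModel:
    """Fitted polynomial y = w0 + w1 z + ... + wk z^k on z = (x - mu)/sigma."""

    order: int
    weights: np.ndarray  # standardized-basis coefficients, ascending order
    x_mean: float
    x_std: float
    training_mse: float = float("nan")

    @property
    def coefficients_raw(self) -> np.ndarray:
        """Coefficients in the raw-x basis (ascending powers of x)."""
        z = Polynomial([-self.x_mean / self.x_std, 1.0 / self.x_std])
        p = Polynomial(self.weights)(z)
        out = np.zeros(self.order + 1)
        out[: len(p.coef)] = p.coef
        return out

    def predict(self, x) -> np.ndarray:
        return predict_polyreg(self, x)


def _design_matrix(z: np.ndarray, order: int) -> np.ndarray:
    return np.vander(z, order + 1, increasing=True)


def fit_polyreg(x, y, order: int = 2) -> PolyRegressionModel:
    """Least-squares fit of a degree-``order`` polynomial of x to y.

    ``x``: per-cycle maximum Doppler frequency (Hz); ``y``: reference depth
    (cm).  Solved with a numerically stable least-squares routine,
    equivalent to the normal-equation closed form at full rank.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < order + 1:
        raise ValueError(
            f"design matrix is rank deficient: need at least {order + 1} "
            f"distinct x values, got {np.unique(x).size}"
        )
    mu = float(x.mean())
    sigma = float(x.std())
    if sigma == 0.0:
        sigma = 1.0
    z = (x - mu) / sigma
    X = _design_matrix(z, order)
    w, *_ = np.linalg.lstsq(X, y, rcond=None)
    mse = float(np.mean((X @ w - y) ** 2))
    return PolyRegressionModel(
        order=order, weights=w, x_mean=mu, x_std=sigma, training_mse=mse
    )


def predict_polyreg(model: PolyRegressionModel, x) -> np.ndarray:
    """Evaluate the fitted polynomial at x (vectorized), in cm."""
    x = np.asarray(x, dtype=float)
    z = (x - model.x_mean) / model.x_std
    return Polynomial(model.weights)(z)
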