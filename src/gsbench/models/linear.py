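"""Penalized linear regression: LASSO and Elastic Net.

Objective (bias w0 unpenalized):

    min_w  1/2 ||y - X* w||^2  +  alpha * Omega(w),
    Omega(w) = l1_ratio * ||w||_1 + (1 - l1_ratio) * ||w||_2^2,

so ``l1_ratio = 1`` recovers LASSO.  The solver is scikit-learn's coordinate
descent with its (alpha, l1_ratio) re-parameterized exactly onto this
objective; the attained objective value is exposed for oracle checks.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import ElasticNet as _SkEN

from .base import HyperparameterSpace, Param, PredictionModel


def penalized_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, w0: float,
                        alpha: float, l1_ratio: float) -> float:
    r = y - X @ w - w0
    return float(0.5 * r @ r + alpha * (l1_ratio * np.abs(w).sum()
                                        + (1.0 - l1_ratio) * w @ w))


def fit_penalized_linear(X: np.ndarray, y: np.ndarray, alpha: float,
                         l1_ratio: float, max_iter: int = 5000, tol: float = 1e-4):
    """Fit the objective above; returns the sklearn estimator plus (w, w0, objective)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if not (0 <= l1_ratio <= 1):
        raise ValueError(f"l1_ratio must be in [0,1], got {l1_ratio}")
    n = X.shape[0]
    # map onto sklearn's objective 1/(2n)||r||^2 + a*(l*||w||_1 + (1-l)/2*||w||_2^2):
    # scaling by n gives L1 weight n*a*l and L2 weight n*a*(1-l)/2.
    A = alpha * l1_ratio          # wanted L1 weight
    B = alpha * (1.0 - l1_ratio)  # wanted L2 weight
    na = A + 2.0 * B
    if na == 0:
        raise ValueError("alpha * Omega vanishes; nothing to fit")
    l_sk = A / na
    est = _SkEN(alpha=na / n, l1_ratio=l_sk, fit_intercept=True, max_iter=max_iter,
                tol=tol)
    est.fit(X, y)
    w = est.coef_.copy()
    w0 = float(est.intercept_)
    obj = penalized_objective(X, y, w, w0, alpha, l1_ratio)
    return est, w, w0, obj


class ElasticNetModel(PredictionModel):
    name = "elasticnet"
    encoding = "additive012"

    def __init__(self, seed: int = 0, alpha: float = 1.0, l1_ratio: float = 0.5) -> None:
        super().__init__(seed=seed, alpha=alpha, l1_ratio=l1_ratio)
        self.alpha = alpha
        self.l1_ratio = l1_ratio

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(
            Param("alpha", "log-real", 1e-3, 1e3),
            Param("l1_ratio", "real", 0.01, 1.0),
        )

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.est_, self.w_, self.w0_, self.objective_ = fit_penalized_linear(
            X, y, self.alpha, self.l1_ratio
        )

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w_ + self.w0_

    def _importance(self) -> np.ndarray:
        return np.abs(self.w_)


class LassoModel(ElasticNetModel):
    name = "lasso"

    def __init__(self, seed: int = 0, alpha: float = 1.0) -> None:
        PredictionModel.__init__(self, seed=seed, alpha=alpha)
        self.alpha = alpha
        self.l1_ratio = 1.0

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(Param("alpha", "log-real", 1e-3, 1e3))
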