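"""Ridge-regression BLUP with REML variance components.

Model: y = mu 1 + X w + e, with marker effects w ~ N(0, sigma2_g I) and
residuals e ~ N(0, sigma2_e I).  The shrinkage factor is the variance ratio
lambda = sigma2_e / sigma2_g, estimated by maximizing the restricted
likelihood profiled over lambda after an eigendecomposition of the marker
cross-product kernel K = X X' projected onto the intercept's complement.
Predictions from the marker-effect form (mu + X_new w) coincide with the
kernel (GBLUP) form (mu + K_new (K + lambda I)^-1 (y - mu 1)) exactly, since
K_new = X_new X'.

The centered -1/0/1 coding is the conventional input for this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .base import HyperparameterSpace, PredictionModel

LAMBDA_BOUNDS = (1e-5, 1e5)


@dataclass
class RRBLUPFit:
    mu: float
    w: np.ndarray
    sigma2_g: float
    sigma2_e: float
    lam: float


def _profile_reml_neg_loglik(log_lam: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    lam = np.exp(log_lam)
    d = xi + lam
    n1 = xi.size
    return float(n1 * np.log(eta2 @ (1.0 / d)) + np.log(d).sum())


def fit_rrblup(X: np.ndarray, y: np.ndarray, lam: float | None = None) -> RRBLUPFit:
    """REML fit; pass ``lam`` to bypass REML and solve the ridge system directly."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all marker columns constant; model is degenerate")

    K = X @ X.T
    if lam is None:
        # orthonormal basis of the intercept's complement via QR of [1 | I]
        Q, _ = linalg.qr(np.ones((n, 1)), mode="full")
        Q2 = Q[:, 1:]                      # n x (n-1)
        M = Q2.T @ K @ Q2
        xi, V = np.linalg.eigh(M)
        xi = np.clip(xi, 0.0, None)
        eta = V.T @ (Q2.T @ y)
        eta2 = eta**2
        res = optimize.minimize_scalar(
            _profile_reml_neg_loglik,
            bounds=(np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])),
            args=(xi, eta2),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        sigma2_g = float(eta2 @ (1.0 / (xi + lam)) / (n - 1))
        sigma2_e = lam * sigma2_g
    else:
        sigma2_g = float("nan")
        sigma2_e = float("nan")

    C = K + lam * np.eye(n)
    cf = linalg.cho_factor(C)
    ones = np.ones(n)
    Ci_y = linalg.cho_solve(cf, y)
    Ci_1 = linalg.cho_solve(cf, ones)
    mu = float(ones @ Ci_y / (ones @ Ci_1))
    alpha = linalg.cho_solve(cf, y - mu * ones)
    w = X.T @ alpha
    fit = RRBLUPFit(mu=mu, w=w, sigma2_g=sigma2_g, sigma2_e=sigma2_e, lam=lam)
    fit._alpha = alpha          # kernel-form dual coefficients
    fit._X_train = X
    return fit


def predict_marker_form(fit: RRBLUPFit, X_new: np.ndarray) -> np.ndarray:
    return fit.mu + np.asarray(X_new, dtype=np.float64) @ fit.w


def predict_kernel_form(fit: RRBLUPFit, X_new: np.ndarray) -> np.ndarray:
    K_new = np.asarray(X_new, dtype=np.float64) @ fit._X_train.T
    return fit.mu + K_new @ fit._alpha


class RRBLUP(PredictionModel):
    name = "rrblup"
    encoding = "additive_centered"

    def __init__(self, seed: int = 0, lam: float | None = None) -> None:
        super().__init__(seed=seed, lam=lam)
        self.lam = lam

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        # variance components come from REML, not from the tuner
        return HyperparameterSpace()

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.fit_ = fit_rrblup(X, y, lam=self.lam)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return predict_marker_form(self.fit_, X)

    def _importance(self) -> np.ndarray:
        return np.abs(self.fit_.w)
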