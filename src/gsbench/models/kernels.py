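"""Support vector regression behind the model contract.

The epsilon-insensitive objective (margin tube of width epsilon around the
targets, slack penalized by C) is solved by scikit-learn's libsvm wrapper.
Inputs and targets are standardized on the training data only; the tube width
is parameterized as a fraction of the training-phenotype standard deviation so
its scale is trait-independent.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVR as _SkSVR

from .base import HyperparameterSpace, Param, PredictionModel, Standardizer


class SVRModel(PredictionModel):
    name = "svr"
    encoding = "additive012"

    def __init__(self, seed: int = 0, C: float = 1.0, epsilon_frac: float = 0.1,
                 kernel: str = "rbf") -> None:
        super().__init__(seed=seed, C=C, epsilon_frac=epsilon_frac, kernel=kernel)
        if C <= 0:
            raise ValueError(f"C must be positive, got {C}")
        if epsilon_frac < 0:
            raise ValueError(f"epsilon_frac must be non-negative, got {epsilon_frac}")
        self.C = C
        self.epsilon_frac = epsilon_frac
        self.kernel = kernel

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(
            Param("C", "log-real", 1e-2, 1e3),
            Param("epsilon_frac", "real", 0.01, 1.0),
            Param("kernel", "categorical", choices=["linear", "rbf"]),
        )

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.scaler_ = Standardizer().fit(X)
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std(ddof=0)) or 1.0
        ys = (y - self.y_mean_) / self.y_sd_
        # tube width in standardized-y units: epsilon_frac * sd(y) / sd(y) = epsilon_frac
        # hard iteration cap: ill-conditioned (large-C, signal-free) fits
        # otherwise stall the tuner without improving their objective
        self.est_ = _SkSVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon_frac,
                           max_iter=200_000)
        self.est_.fit(self.scaler_.transform(X), ys)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return self.est_.predict(self.scaler_.transform(X)) * self.y_sd_ + self.y_mean_
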