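"""Tree ensembles: random forest (bagging) and XGBoost (gradient boosting).

Both delegate to established solvers; the contract adds seeded determinism
and impurity/gain-based feature importances normalized to sum to one.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from .base import HyperparameterSpace, Param, PredictionModel


def _normalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else v


class RandomForestModel(PredictionModel):
    name = "rf"
    encoding = "additive012"

    def __init__(self, seed: int = 0, n_estimators: int = 300, max_depth: int = 10,
                 max_features: float = 0.3) -> None:
        super().__init__(seed=seed, n_estimators=n_estimators, max_depth=max_depth,
                         max_features=max_features)

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(
            Param("n_estimators", "int", 100, 1000),
            Param("max_depth", "int", 2, 20),
            Param("max_features", "real", 0.1, 1.0),
        )

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.est_ = RandomForestRegressor(
            n_estimators=int(self.params["n_estimators"]),
            max_depth=int(self.params["max_depth"]),
            max_features=float(self.params["max_features"]),
            random_state=self.seed,
            n_jobs=1,
        )
        self.est_.fit(X, y)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return self.est_.predict(X)

    def _importance(self) -> np.ndarray:
        # mean impurity decrease per feature, normalized across markers
        return _normalize(np.asarray(self.est_.feature_importances_, dtype=np.float64))


class XGBoostModel(PredictionModel):
    name = "xgb"
    encoding = "additive012"

    def __init__(self, seed: int = 0, n_estimators: int = 300, learning_rate: float = 0.1,
                 max_depth: int = 4, subsample: float = 1.0) -> None:
        super().__init__(seed=seed, n_estimators=n_estimators, learning_rate=learning_rate,
                         max_depth=max_depth, subsample=subsample)

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(
            Param("n_estimators", "int", 50, 1000),
            Param("learning_rate", "log-real", 1e-3, 0.3),
            Param("max_depth", "int", 2, 10),
            Param("subsample", "real", 0.5, 1.0),
        )

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.est_ = XGBRegressor(
            n_estimators=int(self.params["n_estimators"]),
            learning_rate=float(self.params["learning_rate"]),
            max_depth=int(self.params["max_depth"]),
            subsample=float(self.params["subsample"]),
            random_state=self.seed,
            n_jobs=1,
            verbosity=0,
        )
        self.est_.fit(X, y)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return self.est_.predict(X).astype(np.float64)

    def _importance(self) -> np.ndarray:
        imp = np.asarray(self.est_.feature_importances_, dtype=np.float64)
        return _normalize(imp)
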