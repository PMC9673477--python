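"""The uniform prediction-model contract and hyperparameter-space description.

Every model family is a :class:`PredictionModel` subclass declaring its
required genotype encoding and a :class:`HyperparameterSpace`; the evaluation
harness supplies the declared encoding and drives ``fit`` / ``predict`` /
``importance`` without knowing the family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genotypes import EncodedMatrix


class UnsupportedImportanceError(RuntimeError):
    """Raised by models without a per-marker feature importance."""


@dataclass
class Param:
    """One tunable hyperparameter.

    ``kind`` is one of ``real``, ``log-real``, ``int``, ``categorical``;
    numeric kinds carry ``(low, high)`` bounds, categorical carries choices.
    """

    name: str
    kind: str
    low: float | None = None
    high: float | None = None
    choices: list | None = None

    def __post_init__(self) -> None:
        if self.kind in ("real", "log-real", "int"):
            if self.low is None or self.high is None or not np.isfinite([self.low, self.high]).all():
                raise ValueError(f"{self.name}: numeric bounds must be finite")
            if self.low >= self.high:
                raise ValueError(f"{self.name}: low >= high")
            if self.kind == "log-real" and self.low <= 0:
                raise ValueError(f"{self.name}: log-real bounds must be positive")
        elif self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: empty choices")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


class HyperparameterSpace(dict):
    """Mapping of parameter name to :class:`Param`."""

    @classmethod
    def of(cls, *params: Param) -> "HyperparameterSpace":
        return cls({p.name: p for p in params})


def as_array(X) -> np.ndarray:
    """Accept either an ndarray or an EncodedMatrix and return the value matrix."""
    if isinstance(X, EncodedMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


class PredictionModel:
    """Contract: construct with hyperparameters, then fit / predict / importance.

    Subclasses set ``name`` and ``encoding`` class attributes and implement
    ``_fit(X, y)`` and ``_predict(X)`` on plain arrays.  ``importance`` returns
    a per-marker vector for the families that define one and raises
    :class:`UnsupportedImportanceError` otherwise.
    """

    name: str = "abstract"
    encoding: str = "additive012"

    def __init__(self, seed: int = 0, **params) -> None:
        self.seed = seed
        self.params = params
        self._fitted = False
        self._onehot_groups = None

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace()

    def fit(self, X, y) -> "PredictionModel":
        if isinstance(X, EncodedMatrix):
            self._onehot_groups = X.feature_group
        Xv = as_array(X)
        y = np.asarray(y, dtype=np.float64)
        if Xv.shape[0] != y.shape[0]:
            raise ValueError(f"X has {Xv.shape[0]} rows but y has {y.shape[0]}")
        if not np.isfinite(y).all():
            raise ValueError("non-finite phenotype values")
        self._fit(Xv, y)
        self._fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError(f"{self.name}: fit before predict")
        return self._predict(as_array(X))

    def importance(self) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError(f"{self.name}: fit before importance")
        return self._importance()

    # -- subclass surface ---------------------------------------------------

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        raise NotImplementedError

    def _predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _importance(self) -> np.ndarray:
        raise UnsupportedImportanceError(f"{self.name} defines no per-marker importance")


class Standardizer:
    """Per-feature standardization fitted on training data only (leak-free)."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_
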