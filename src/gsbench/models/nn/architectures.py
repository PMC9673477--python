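"""The three genotype-to-phenotype network families.

* **MLP** — N blocks of [dense → batch norm → activation → dropout] on the
  additive encoding, then a linear output unit.
* **CNN** — N blocks of [1-D convolution → batch norm → activation → dropout]
  over the one-hot channel tensor, max pooling, flatten, one dense block,
  linear output.
* **LCNN** — one locally connected block (position-specific filters) with
  batch norm, dropout and max pooling, flatten, N dense blocks, linear output.

All train with Adam on squared error under validation early stopping; the
additive inputs of the MLP are standardized on training data, one-hot inputs
are left as indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ...genotypes import EncodedMatrix
from ..base import HyperparameterSpace, Param, PredictionModel, Standardizer
from .layers import (BatchNorm, Conv1d, Dense, Dropout, Flatten, LocallyConnected1d,
                     MaxPool1d, ReLU, Sequential, Tanh, conv_out_len)
from .training import predict_network, train_network

UNIT_CHOICES = [32, 64, 128, 256, 512, 1024]
FILTER_CHOICES = [4, 8, 16]


@dataclass
class NeuralArchitecture:
    family: str                    # mlp | cnn | lcnn
    n_blocks: int = 1
    units: int = 64
    filters: int = 8
    kernel_size: int = 5
    stride: int = 2
    pool: int = 2
    dropout: float = 0.1
    activation: str = "relu"
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 10

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _act(name: str):
    return ReLU() if name == "relu" else Tanh()


def build_network(arch: NeuralArchitecture, n_features: int, n_channels: int,
                  rng: np.random.Generator) -> Sequential:
    """Assemble the layer stack; raises before training on infeasible shapes."""
    layers = []
    if arch.family == "mlp":
        d = n_features
        for _ in range(arch.n_blocks):
            layers += [Dense(d, arch.units, rng), BatchNorm(arch.units),
                       _act(arch.activation), Dropout(arch.dropout, rng)]
            d = arch.units
        layers.append(Dense(d, 1, rng))
    elif arch.family == "cnn":
        length, ch = n_features, n_channels
        for _ in range(arch.n_blocks):
            length = conv_out_len(length, arch.kernel_size, arch.stride)
            layers += [Conv1d(ch, arch.filters, arch.kernel_size, arch.stride, rng),
                       BatchNorm(arch.filters), _act(arch.activation),
                       Dropout(arch.dropout, rng)]
            ch = arch.filters
        layers.append(MaxPool1d(arch.pool))
        length //= arch.pool
        if length == 0:
            raise ValueError("input too short for the kernel/stride/pool configuration")
        layers.append(Flatten())
        d = ch * length
        layers += [Dense(d, arch.units, rng), BatchNorm(arch.units),
                   _act(arch.activation), Dropout(arch.dropout, rng),
                   Dense(arch.units, 1, rng)]
    elif arch.family == "lcnn":
        length = conv_out_len(n_features, arch.kernel_size, arch.stride)
        layers += [LocallyConnected1d(n_channels, arch.filters, arch.kernel_size,
                                      arch.stride, n_features, rng),
                   BatchNorm(arch.filters), _act(arch.activation),
                   Dropout(arch.dropout, rng), MaxPool1d(arch.pool)]
        length //= arch.pool
        if length == 0:
            raise ValueError("input too short for the kernel/stride/pool configuration")
        layers.append(Flatten())
        d = arch.filters * length
        for _ in range(arch.n_blocks):
            layers += [Dense(d, arch.units, rng), BatchNorm(arch.units),
                       _act(arch.activation), Dropout(arch.dropout, rng)]
            d = arch.units
        layers.append(Dense(d, 1, rng))
    else:
        raise ValueError(f"unknown family {arch.family!r}")
    return Sequential(layers)


def build_and_train_network(
    arch: NeuralArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[Sequential, dict]:
    """Build per the block description, split off a validation set, train."""
    rng = np.random.default_rng(seed)
    n_channels = X.shape[1] if X.ndim == 3 else 0
    n_features = X.shape[2] if X.ndim == 3 else X.shape[1]
    net = build_network(arch, n_features, n_channels, rng)

    n = X.shape[0]
    if validation_fraction > 0 and n >= 5:
        n_val = max(1, int(round(validation_fraction * n)))
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    else:
        X_tr, y_tr, X_val, y_val = X, y, None, None

    history = train_network(
        net, X_tr, y_tr, X_val, y_val, lr=arch.lr, batch_size=arch.batch_size,
        max_epochs=arch.max_epochs, patience=arch.patience, rng=rng,
    )
    return net, history


class _NeuralModel(PredictionModel):
    family = "mlp"

    def __init__(self, seed: int = 0, **arch_params) -> None:
        super().__init__(seed=seed, **arch_params)
        self.arch_params = arch_params

    def _make_arch(self) -> NeuralArchitecture:
        return NeuralArchitecture(family=self.family, **{
            k: v for k, v in self.arch_params.items() if v is not None
        })

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        return X

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std(ddof=0)) or 1.0
        Xp = self._prepare_fit(X)
        self.net_, self.history_ = build_and_train_network(
            self._make_arch(), Xp, (y - self.y_mean_) / self.y_sd_, seed=self.seed
        )

    def _prepare_fit(self, X: np.ndarray) -> np.ndarray:
        return self._prepare(X)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return predict_network(self.net_, self._prepare(X)) * self.y_sd_ + self.y_mean_


class MLPModel(_NeuralModel):
    name = "mlp"
    family = "mlp"
    encoding = "additive012"

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(
            Param("n_blocks", "int", 1, 4),
            Param("units", "categorical", choices=UNIT_CHOICES),
            Param("dropout", "real", 0.0, 0.5),
            Param("lr", "log-real", 1e-4, 1e-2),
            Param("activation", "categorical", choices=["relu", "tanh"]),
        )

    def _prepare_fit(self, X: np.ndarray) -> np.ndarray:
        self.scaler_ = Standardizer().fit(X)
        return self.scaler_.transform(X)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        return self.scaler_.transform(X)


class _ChannelModel(_NeuralModel):
    """Shared logic for the one-hot (channel-tensor) families."""

    encoding = "onehot"

    def fit(self, X, y):
        if not isinstance(X, EncodedMatrix) or X.feature_group is None:
            raise ValueError(f"{self.name} requires a one-hot EncodedMatrix input")
        self._groups = X.feature_group
        self._n_markers = len(X.marker_ids)
        return super().fit(X, y)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((X.shape[0], 3, self._n_markers))
        for col, (j, state) in enumerate(self._groups):
            out[:, state, j] = X[:, col]
        return out

    def predict(self, X):
        Xv = X.values if isinstance(X, EncodedMatrix) else np.asarray(X, dtype=np.float64)
        if not self._fitted:
            raise RuntimeError(f"{self.name}: fit before predict")
        return predict_network(self.net_, self._prepare(Xv)) * self.y_sd_ + self.y_mean_


class CNNModel(_ChannelModel):
    name = "cnn"
    family = "cnn"

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(
            Param("n_blocks", "int", 1, 3),
            Param("filters", "categorical", choices=FILTER_CHOICES),
            Param("kernel_size", "int", 3, 9),
            Param("stride", "int", 1, 3),
            Param("units", "categorical", choices=UNIT_CHOICES),
            Param("dropout", "real", 0.0, 0.5),
            Param("lr", "log-real", 1e-4, 1e-2),
            Param("activation", "categorical", choices=["relu", "tanh"]),
        )


class LCNNModel(_ChannelModel):
    name = "lcnn"
    family = "lcnn"

    @classmethod
    def search_space(cls) -> HyperparameterSpace:
        return HyperparameterSpace.of(
            Param("n_blocks", "int", 1, 3),
            Param("filters", "categorical", choices=FILTER_CHOICES),
            Param("kernel_size", "int", 3, 9),
            Param("stride", "int", 1, 3),
            Param("units", "categorical", choices=UNIT_CHOICES),
            Param("dropout", "real", 0.0, 0.5),
            Param("lr", "log-real", 1e-4, 1e-2),
            Param("activation", "categorical", choices=["relu", "tanh"]),
        )
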