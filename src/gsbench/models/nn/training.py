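"""Mini-batch Adam training with validation-based early stopping."""

from __future__ import annotations

import numpy as np

from .layers import Adam, Sequential


def train_network(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None,
    y_val: np.ndarray | None,
    lr: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 150,
    patience: int = 10,
    rng: np.random.Generator | None = None,
) -> dict:
    """Minimize mean squared error; monitor validation loss and restore the
    best weights once ``patience`` epochs pass without improvement.

    Returns a history dict with per-epoch train/validation losses and the
    epoch whose weights were kept.
    """
    rng = rng or np.random.default_rng(0)
    n = X.shape[0]
    batch_size = min(batch_size, n)
    opt = Adam(net.params(), lr=lr)
    use_val = X_val is not None and len(X_val) > 0

    best_loss = np.inf
    best_state = net.state()
    best_epoch = 0
    since_best = 0
    history = {"train_loss": [], "val_loss": [], "best_epoch": 0, "stopped_epoch": None}

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            out = net.forward(X[idx], train=True).ravel()
            resid = out - y[idx]
            ep_loss += float(resid @ resid)
            grad = (2.0 * resid / idx.size).reshape(-1, 1)
            net.backward(grad)
            opt.step(net.grads())
        history["train_loss"].append(ep_loss / n)

        if use_val:
            val_out = net.forward(X_val, train=False).ravel()
            val_loss = float(np.mean((val_out - y_val) ** 2))
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_state = net.state()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    history["stopped_epoch"] = epoch
                    break

    if use_val:
        net.load_state(best_state)
        history["best_epoch"] = best_epoch
    return history


def predict_network(net: Sequential, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    outs = [net.forward(X[i:i + batch_size], train=False).ravel()
            for i in range(0, X.shape[0], batch_size)]
    return np.concatenate(outs) if outs else np.empty(0)
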