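"""Evaluation metric: explained variance of predictions."""

from __future__ import annotations

import numpy as np


def explained_variance(y: np.ndarray, y_hat: np.ndarray) -> float:
    """v = 1 - Var(y - y_hat) / Var(y).

    Ranges over (-inf, 1]; invariant to adding a constant to the predictions;
    a constant predictor scores exactly 0.  Sample variances use the n-1
    convention (the ratio is invariant to the divisor as long as it is
    applied consistently).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be 1-D with equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    var_y = np.var(y, ddof=1)
    if var_y == 0:
        raise ValueError("explained variance undefined for constant y")
    return float(1.0 - np.var(y - y_hat, ddof=1) / var_y)
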