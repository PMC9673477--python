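"""Stratified nested cross-validation splits.

Samples are grouped into quantile bins of the phenotype so that every fold
sees approximately the same phenotypic distribution, then outer (test) and
inner (validation) folds are drawn stratified by bin.  Bins too small to
appear in every fold are merged upward into their neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass
class SplitPlan:
    """Outer test folds and, per outer fold, inner (train, validation) pairs.

    All index arrays refer to positions in the original sample vector.
    """

    outer_folds: list[dict]        # {"train": idx, "test": idx}
    inner_folds: list[list[tuple[np.ndarray, np.ndarray]]]
    bin_labels: np.ndarray
    seed: int

    @property
    def n_outer(self) -> int:
        return len(self.outer_folds)


def quantile_bins(y: np.ndarray, n_bins: int, min_count: int) -> np.ndarray:
    """Quantile-bin labels with small bins merged into the next bin up."""
    y = np.asarray(y, dtype=float)
    edges = np.unique(np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1]))
    labels = np.searchsorted(edges, y, side="left")
    # merge forward until every occupied bin holds at least min_count samples
    uniq = np.unique(labels)
    for i, lab in enumerate(uniq):
        count = int((labels == lab).sum())
        if count < min_count:
            target = uniq[i + 1] if i + 1 < len(uniq) else uniq[i - 1] if i > 0 else lab
            labels[labels == lab] = target
            return quantile_relabel(labels, min_count)
    return labels


def quantile_relabel(labels: np.ndarray, min_count: int) -> np.ndarray:
    # re-run the merge pass until stable
    while True:
        uniq = np.unique(labels)
        if len(uniq) == 1:
            return labels
        merged = False
        for i, lab in enumerate(uniq):
            if int((labels == lab).sum()) < min_count:
                target = uniq[i + 1] if i + 1 < len(uniq) else uniq[i - 1]
                labels[labels == lab] = target
                merged = True
                break
        if not merged:
            return labels


def stratified_nested_splits(
    y: np.ndarray,
    n_outer: int = 3,
    n_inner: int = 5,
    n_bins: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Build the nested split plan (default 3 outer x 5 inner folds)."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_outer * n_inner:
        raise ValueError(f"{n} samples cannot support {n_outer}x{n_inner} nested folds")

    bins = quantile_bins(y, n_bins, min_count=n_outer)
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    outer_folds: list[dict] = []
    inner_folds: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for i, (train, test) in enumerate(outer.split(np.zeros(n), bins)):
        outer_folds.append({"train": train, "test": test})
        sub_bins = quantile_relabel(bins[train].copy(), min_count=n_inner)
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed + 1 + i)
        pairs = [(train[tr], train[va])
                 for tr, va in inner.split(np.zeros(len(train)), sub_bins)]
        inner_folds.append(pairs)
    return SplitPlan(outer_folds=outer_folds, inner_folds=inner_folds,
                     bin_labels=bins, seed=seed)
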