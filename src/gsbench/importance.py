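"""Feature-importance aggregation across outer folds and scoring against
simulated ground truth.

For each outer fold a model yields one importance vector (absolute
coefficients for the linear/Bayesian families, normalized impurity reduction
for the tree ensembles).  Per fold the top-k magnitudes are min-max
normalized to [0, 1]; every marker that reaches the top k in at least one
fold receives the average of its normalized values over *all* folds
(contributing zero where absent).  A marker with nonzero averaged importance
counts as an important feature; a second, filtered variant drops importances
below 1% of the model's largest.  Against ground truth we report how many
important features are true background SNPs (the true positive rate), how
many causal SNPs were detected and at which ranks, and the Pearson
correlation between simulated effect sizes and averaged importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GroundTruth

__all__ = [
    "ImportanceReport",
    "top_k_select",
    "aggregate_across_folds",
    "relative_filter",
    "score_against_truth",
    "effect_importance_correlation",
]


@dataclass
class ImportanceReport:
    model_name: str
    averaged: dict[int, float]             # marker index -> fold-averaged importance
    n_important: int
    n_important_filtered: int
    background_found: int
    tpr: float
    background_found_filtered: int
    tpr_filtered: float
    causal_total: int
    causal_found: int
    causal_ranks: list[int]                # 1-based, among important features
    pearson_r: float | None = None
    extras: dict = field(default_factory=dict)


def top_k_select(importance: np.ndarray, k: int = 1000) -> np.ndarray:
    """Indices of the k largest-magnitude importances, descending.

    Ties break by marker order (stable sort); k is capped at the vector
    length, so a short vector is returned whole, nonzero entries first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.abs(np.asarray(importance, dtype=float))
    order = np.argsort(-v, kind="stable")
    return order[: min(k, v.size)]


def aggregate_across_folds(fold_importances: list[np.ndarray], k: int = 1000) -> dict[int, float]:
    """Fold-averaged, min-max normalized importance for every marker that is
    in the top k of at least one fold."""
    if not fold_importances:
        raise ValueError("need at least one fold importance vector")
    n_folds = len(fold_importances)
    sums: dict[int, float] = {}
    members: set[int] = set()
    for f, vec in enumerate(fold_importances):
        v = np.abs(np.asarray(vec, dtype=float))
        top = top_k_select(v, k)
        members.update(int(j) for j in top)
        lo, hi = v[top].min(), v[top].max()
        if hi == lo:
            warnings.warn(f"fold {f}: constant importance vector contributes zeros")
            continue
        norm = (v[top] - lo) / (hi - lo)
        for j, val in zip(top, norm):
            sums[int(j)] = sums.get(int(j), 0.0) + float(val)
    return {j: sums.get(j, 0.0) / n_folds for j in sorted(members)}


def relative_filter(averaged: dict[int, float], fraction: float = 0.01) -> dict[int, float]:
    """Keep markers whose |importance| is at least ``fraction`` of the maximum."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0,1)")
    if not averaged:
        return {}
    cutoff = fraction * max(abs(v) for v in averaged.values())
    return {j: v for j, v in averaged.items() if abs(v) >= cutoff}


def _important(averaged: dict[int, float]) -> dict[int, float]:
    return {j: v for j, v in averaged.items() if v != 0.0}


def _ranks(important: dict[int, float], targets: np.ndarray) -> list[int]:
    # rank 1 = largest averaged importance; ties stable by marker index
    items = sorted(important.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    pos = {j: r + 1 for r, (j, _) in enumerate(items)}
    return sorted(pos[int(t)] for t in targets if int(t) in pos)


def score_against_truth(
    averaged: dict[int, float],
    truth: GroundTruth,
    model_name: str = "",
    filter_fraction: float = 0.01,
) -> ImportanceReport:
    """Summarize causal/background recovery of one model's averaged importances."""
    important = _important(averaged)
    filtered = _important(relative_filter(averaged, filter_fraction)) if averaged else {}
    bg = set(int(j) for j in truth.background_indices)
    causal = np.asarray(truth.causal_indices, dtype=int)

    n_imp = len(important)
    n_filt = len(filtered)
    bg_found = sum(1 for j in important if j in bg)
    bg_found_f = sum(1 for j in filtered if j in bg)
    report = ImportanceReport(
        model_name=model_name,
        averaged=averaged,
        n_important=n_imp,
        n_important_filtered=n_filt,
        background_found=bg_found,
        tpr=bg_found / n_imp if n_imp else 0.0,
        background_found_filtered=bg_found_f,
        tpr_filtered=bg_found_f / n_filt if n_filt else 0.0,
        causal_total=int(causal.size),
        causal_found=sum(1 for j in causal if int(j) in important),
        causal_ranks=_ranks(important, causal),
    )
    return report


def effect_importance_correlation(
    truth: GroundTruth, averaged: dict[int, float]
) -> tuple[float, pd.DataFrame]:
    """Pearson r between |simulated effect| and averaged importance.

    Pairs only markers where both quantities are nonzero (causal markers use
    their beta, background markers their gamma); the paired table is returned
    for scatter plotting.  Raises with fewer than 3 pairs.
    """
    effects: dict[int, tuple[float, bool]] = {}
    for j, g in zip(truth.background_indices, truth.gamma):
        effects[int(j)] = (abs(float(g)), False)
    for pos, j in enumerate(truth.causal_indices):
        effects[int(j)] = (abs(float(truth.beta[pos])), True)

    rows = []
    for j, imp in averaged.items():
        if imp == 0.0 or j not in effects:
            continue
        eff, is_causal = effects[j]
        if eff == 0.0:
            continue
        rows.append((j, eff, imp, is_causal))
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} nonzero effect/importance pairs; need >= 3")
    table = pd.DataFrame(rows, columns=["marker", "effect_size", "importance", "is_causal"])
    r = float(stats.pearsonr(table["effect_size"], table["importance"]).statistic)
    return r, table
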