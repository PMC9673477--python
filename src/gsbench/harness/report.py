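"""Tabular and graphical summaries of benchmark results."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .experiment import EvaluationResult


def results_table(results: list[EvaluationResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes x models matrices of mean explained variance and its sd."""
    if not results:
        raise ValueError("no results to summarize")
    phenos = list(dict.fromkeys(r.phenotype for r in results))
    models = list(dict.fromkeys(r.model_name for r in results))
    mean = pd.DataFrame(index=phenos, columns=models, dtype=float)
    sd = pd.DataFrame(index=phenos, columns=models, dtype=float)
    for r in results:
        mean.loc[r.phenotype, r.model_name] = r.mean
        sd.loc[r.phenotype, r.model_name] = r.sd
    mean.index.name = sd.index.name = "phenotype"
    return mean, sd


def results_heatmap(results: list[EvaluationResult], out_prefix) -> dict[str, str]:
    """Write mean/sd CSV tables and a heatmap figure with best-per-row boxes.

    Returns the paths written, keyed by artifact kind.
    """
    mean, sd = results_table(results)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "mean_csv": str(out_prefix) + "_mean.csv",
        "sd_csv": str(out_prefix) + "_sd.csv",
        "figure": str(out_prefix) + ".png",
    }
    mean.to_csv(paths["mean_csv"])
    sd.to_csv(paths["sd_csv"])

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.9 * mean.shape[1], 1.0 + 0.6 * mean.shape[0])
    )
    arr = mean.to_numpy(dtype=float)
    im = ax.imshow(arr, cmap="RdBu", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(mean.shape[1]), mean.columns, rotation=45, ha="right")
    ax.set_yticks(range(mean.shape[0]), mean.index)
    for i in range(arr.shape[0]):
        with np.errstate(invalid="ignore"):
            best = np.nanargmax(arr[i]) if not np.isnan(arr[i]).all() else None
        for j in range(arr.shape[1]):
            if not np.isnan(arr[i, j]):
                ax.text(j, i, f"{arr[i, j]:.2f}", ha="center", va="center", fontsize=8)
        if best is not None:
            ax.add_patch(plt.Rectangle((best - 0.5, i - 0.5), 1, 1,
                                       fill=False, edgecolor="black", lw=2))
    ax.set_xlabel("prediction model")
    fig.colorbar(im, ax=ax, label="explained variance v")
    fig.tight_layout()
    fig.savefig(paths["figure"], dpi=120)
    plt.close(fig)
    return paths


def best_per_phenotype(results: list[EvaluationResult]) -> dict[str, str]:
    mean, _ = results_table(results)
    return {ph: mean.loc[ph].astype(float).idxmax() for ph in mean.index}
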