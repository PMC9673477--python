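"""The benchmarking loop: per model and outer fold, tune on the inner folds,
refit on the full outer-training data, score on the hold-out test fold."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genotypes import EncodedMatrix, GenotypeMatrix, encode
from ..models import MODEL_REGISTRY, make_model
from ..models.base import UnsupportedImportanceError
from .metrics import explained_variance
from .optimize import TrialRecord, optimize_hyperparameters
from .splits import SplitPlan, stratified_nested_splits

log = logging.getLogger("gsbench")


@dataclass
class EvaluationResult:
    model_name: str
    phenotype: str
    fold_scores: list[float]
    mean: float
    sd: float
    best_params: list[dict]
    fold_importances: list[np.ndarray | None]
    trial_history: list[list[TrialRecord]]
    errors: list[str | None]
    n_trials: int
    seed: int


def _rows(E, idx: np.ndarray):
    """Row-subset an EncodedMatrix (or plain array) without re-fitting anything."""
    if isinstance(E, EncodedMatrix):
        return EncodedMatrix(E.scheme, E.values[idx], E.marker_ids, E.feature_group)
    return np.asarray(E)[idx]


def align_phenotype(G: GenotypeMatrix, y) -> np.ndarray:
    """Align a phenotype Series (indexed by sample id) or array to G's rows."""
    if isinstance(y, pd.Series):
        missing = [s for s in G.sample_ids if s not in y.index]
        if missing:
            raise ValueError(f"phenotype missing for {len(missing)} samples, e.g. {missing[:3]}")
        return y.loc[G.sample_ids].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != G.n_samples:
        raise ValueError(f"phenotype length {y.shape[0]} != {G.n_samples} samples")
    return y


def run_experiment(
    G: GenotypeMatrix,
    y,
    models: list[str],
    n_trials: int = 50,
    pruning_percentile: float = 80.0,
    seed: int = 0,
    n_outer: int = 3,
    n_inner: int = 5,
    n_bins: int = 10,
    phenotype_name: str = "trait",
    model_overrides: dict[str, dict] | None = None,
    split_plan: SplitPlan | None = None,
) -> list[EvaluationResult]:
    """Benchmark the named models on one phenotype under nested CV.

    ``model_overrides`` maps a model name to hyperparameters that are fixed
    (not tuned), e.g. shorter Bayes chains for a reduced-budget run.  Model
    failures are recorded per fold and the experiment continues.
    """
    yv = align_phenotype(G, y)
    plan = split_plan or stratified_nested_splits(yv, n_outer, n_inner, n_bins, seed)
    overrides = model_overrides or {}

    results: list[EvaluationResult] = []
    for name in models:
        if name not in MODEL_REGISTRY:
            raise KeyError(f"unknown model {name!r}")
        cls = MODEL_REGISTRY[name]
        t0 = time.time()
        log.info("model %s: encoding=%s n=%d m=%d trials=%d",
                 name, cls.encoding, G.n_samples, G.n_markers, n_trials)
        E = encode(G, cls.encoding)
        fixed = overrides.get(name)

        fold_scores, best_params, fold_imps, histories, errors = [], [], [], [], []
        for k, fold in enumerate(plan.outer_folds):
            try:
                params, history = optimize_hyperparameters(
                    name, cls.search_space(), E, yv, plan.inner_folds[k],
                    n_trials=n_trials, pruning_percentile=pruning_percentile,
                    seed=seed + 17 * k, fixed_params=fixed,
                )
                model = make_model(name, {**params, **(fixed or {})}, seed=seed + 17 * k)
                model.fit(_rows(E, fold["train"]), yv[fold["train"]])
                v = explained_variance(yv[fold["test"]],
                                       model.predict(_rows(E, fold["test"])))
                try:
                    imp = model.importance()
                except UnsupportedImportanceError:
                    imp = None
                fold_scores.append(v)
                best_params.append(params)
                fold_imps.append(imp)
                histories.append(history)
                errors.append(None)
            except Exception as exc:  # noqa: BLE001 - continue with remaining folds/models
                log.warning("model %s outer fold %d failed: %s", name, k, exc)
                errors.append(f"{type(exc).__name__}: {exc}")
                histories.append([])
                best_params.append({})
                fold_imps.append(None)

        mean = float(np.mean(fold_scores)) if fold_scores else float("nan")
        sd = float(np.std(fold_scores)) if fold_scores else float("nan")
        log.info("model %s: v = %.4f +/- %.4f (%.1fs)", name, mean, sd, time.time() - t0)
        results.append(EvaluationResult(
            model_name=name, phenotype=phenotype_name, fold_scores=fold_scores,
            mean=mean, sd=sd, best_params=best_params, fold_importances=fold_imps,
            trial_history=histories, errors=errors, n_trials=n_trials, seed=seed,
        ))
    return results
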