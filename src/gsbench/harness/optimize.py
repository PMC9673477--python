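"""Sequential model-based hyperparameter search with percentile pruning.

The sampler is a tree-structured-Parzen-estimator style procedure: after a
random warm-up, completed trials are split into a "good" quantile and the
rest, one-dimensional kernel densities are placed over each parameter in the
two groups, candidates are drawn from the good density and scored by the
density ratio.  Trials report one intermediate score per inner fold (the
running mean of fold scores); a trial is pruned when its running mean falls
below the 80th percentile of earlier trials' running means at the same step.
The percentile rule stays inactive until ten trials have completed, since a
percentile over fewer trials is noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..models.base import HyperparameterSpace, Param

N_STARTUP = 10
PRUNER_WARMUP = 10
GOOD_FRACTION = 0.25
N_CANDIDATES = 24


@dataclass
class TrialRecord:
    trial_id: int
    params: dict
    inner_scores: list[float] = field(default_factory=list)
    objective: float | None = None
    pruned: bool = False
    error: str | None = None


def _to_unit(p: Param, v):
    if p.kind == "log-real":
        return (math.log(v) - math.log(p.low)) / (math.log(p.high) - math.log(p.low))
    if p.kind in ("real", "int"):
        return (v - p.low) / (p.high - p.low)
    raise ValueError(p.kind)


def _from_unit(p: Param, u: float):
    u = min(max(u, 0.0), 1.0)
    if p.kind == "log-real":
        return math.exp(math.log(p.low) + u * (math.log(p.high) - math.log(p.low)))
    val = p.low + u * (p.high - p.low)
    return int(round(val)) if p.kind == "int" else val


def _random_params(space: HyperparameterSpace, rng: np.random.Generator) -> dict:
    out = {}
    for name, p in space.items():
        if p.kind == "categorical":
            out[name] = p.choices[rng.integers(len(p.choices))]
        else:
            out[name] = _from_unit(p, float(rng.random()))
    return out


def _kde_logpdf(obs: np.ndarray, x: float) -> float:
    # gaussian bumps on the unit interval; bandwidth shrinks with sample size
    bw = max(0.5 * obs.size ** -0.5, 0.05)
    z = (x - obs) / bw
    dens = np.exp(-0.5 * z * z).sum() / (obs.size * bw * math.sqrt(2 * math.pi))
    return math.log(dens + 1e-12)


def _tpe_params(space: HyperparameterSpace, history: list[TrialRecord],
                rng: np.random.Generator) -> dict:
    done = [t for t in history if t.objective is not None and not t.pruned]
    if len(done) < N_STARTUP:
        return _random_params(space, rng)
    done = sorted(done, key=lambda t: -t.objective)
    n_good = max(2, int(math.ceil(GOOD_FRACTION * len(done))))
    good, bad = done[:n_good], done[n_good:] or done[-2:]

    best_score, best_params = -np.inf, None
    for _ in range(N_CANDIDATES):
        cand, score = {}, 0.0
        for name, p in space.items():
            gv = [t.params[name] for t in good]
            bv = [t.params[name] for t in bad]
            if p.kind == "categorical":
                counts_g = np.array([sum(v == c for v in gv) + 1.0 for c in p.choices])
                counts_b = np.array([sum(v == c for v in bv) + 1.0 for c in p.choices])
                probs_g = counts_g / counts_g.sum()
                probs_b = counts_b / counts_b.sum()
                k = rng.choice(len(p.choices), p=probs_g)
                cand[name] = p.choices[k]
                score += math.log(probs_g[k]) - math.log(probs_b[k])
            else:
                gu = np.array([_to_unit(p, v) for v in gv])
                bu = np.array([_to_unit(p, v) for v in bv])
                bw = max(0.5 * gu.size ** -0.5, 0.05)
                u = float(gu[rng.integers(gu.size)] + bw * rng.standard_normal())
                u = min(max(u, 0.0), 1.0)
                cand[name] = _from_unit(p, u)
                score += _kde_logpdf(gu, u) - _kde_logpdf(bu, u)
        if score > best_score:
            best_score, best_params = score, cand
    return best_params


class Pruner:
    """80th-percentile rule over running-mean intermediate scores per step."""

    def __init__(self, percentile: float = 80.0, warmup: int = PRUNER_WARMUP) -> None:
        self.percentile = percentile
        self.warmup = warmup
        self.step_history: dict[int, list[float]] = {}
        self.n_completed = 0

    def should_prune(self, step: int, running_mean: float) -> bool:
        prev = self.step_history.get(step, [])
        decide = (self.n_completed >= self.warmup and len(prev) > 0
                  and running_mean < np.percentile(prev, self.percentile))
        prev.append(running_mean)
        self.step_history[step] = prev
        return decide

    def trial_completed(self) -> None:
        self.n_completed += 1


def optimize(
    space: HyperparameterSpace,
    evaluate_steps,
    n_trials: int = 200,
    pruning_percentile: float | None = 80.0,
    seed: int = 0,
) -> tuple[dict, list[TrialRecord]]:
    """Maximize the mean per-step score of ``evaluate_steps(params)``.

    ``evaluate_steps`` yields one score per step (inner fold); the objective
    is the mean over all steps.  Returns the best completed trial's
    parameters and the full trial history.  With an empty space a single
    default trial is evaluated.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    pruner = Pruner(pruning_percentile) if pruning_percentile is not None else None
    history: list[TrialRecord] = []
    if not space:
        n_trials = 1

    last_error: Exception | None = None
    for tid in range(n_trials):
        params = {} if not space else _tpe_params(space, history, rng)
        trial = TrialRecord(trial_id=tid, params=params)
        history.append(trial)
        try:
            for score in evaluate_steps(params):
                trial.inner_scores.append(float(score))
                running = float(np.mean(trial.inner_scores))
                if pruner is not None and pruner.should_prune(len(trial.inner_scores), running):
                    trial.pruned = True
                    break
            if not trial.pruned:
                if not trial.inner_scores:
                    raise RuntimeError("evaluate_steps yielded no scores")
                trial.objective = float(np.mean(trial.inner_scores))
                if pruner is not None:
                    pruner.trial_completed()
        except Exception as exc:  # noqa: BLE001 - model failures recorded per trial
            trial.error = f"{type(exc).__name__}: {exc}"
            last_error = exc

    done = [t for t in history if t.objective is not None]
    if not done:
        raise RuntimeError(f"all {n_trials} trials failed; last error: {last_error}")
    best = max(done, key=lambda t: t.objective)
    return best.params, history


def optimize_hyperparameters(
    model_name: str,
    space: HyperparameterSpace,
    X_encoded,
    y: np.ndarray,
    inner_folds: list[tuple[np.ndarray, np.ndarray]],
    n_trials: int = 200,
    pruning_percentile: float = 80.0,
    seed: int = 0,
    fixed_params: dict | None = None,
):
    """Tune one model on the inner folds of a single outer fold.

    The objective is the mean inner-fold explained variance; intermediate
    (running-mean) results feed the percentile pruner.
    """
    from ..models import make_model
    from .experiment import _rows
    from .metrics import explained_variance

    y = np.asarray(y, dtype=float)

    def evaluate_steps(params):
        merged = {**params, **(fixed_params or {})}
        for tr, va in inner_folds:
            model = make_model(model_name, merged, seed=seed)
            model.fit(_rows(X_encoded, tr), y[tr])
            yield explained_variance(y[va], model.predict(_rows(X_encoded, va)))

    return optimize(space, evaluate_steps, n_trials=n_trials,
                    pruning_percentile=pruning_percentile, seed=seed)
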