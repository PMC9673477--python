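"""Benchmark prediction models on simulated phenotypes under nested CV.

Desk-scale counterpart of the full heatmap experiment: a 1,000 x 2,000
synthetic panel, a chosen subset of configurations at h = 0.95, and a reduced
trial budget (default 25, against 200 at full scale).  Writes per-fold scores,
the mean/sd heatmap tables and figure, and per-fold importance vectors under
results/benchmark/.

Run from the repository root:
  python analysis/02_benchmark_models.py [--models rrblup,bayes_b,lasso,elasticnet,rf,xgb]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gsbench.genotypes import generate_synthetic_genotypes
from gsbench.harness import results_heatmap, run_experiment
from gsbench.simulate import get_config, simulate, write_truth_sidecar


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--models", default="rrblup,bayes_b,lasso,elasticnet,rf,xgb")
    ap.add_argument("--configs", default="C,I")
    ap.add_argument("--trials", type=int, default=25)
    ap.add_argument("--n-markers", type=int, default=2000)
    ap.add_argument("--out", default="results/benchmark")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    models = args.models.split(",")
    G = generate_synthetic_genotypes(1000, args.n_markers, seed=args.seed)
    # shorter Bayes chains at desk scale; the full-scale default is 6000/1000
    overrides = {"bayes_a": {"n_iter": 1500, "burn_in": 500},
                 "bayes_b": {"n_iter": 1500, "burn_in": 500},
                 "bayes_c": {"n_iter": 1500, "burn_in": 500}}

    all_results, rows = [], []
    for name in args.configs.split(","):
        sp = simulate(get_config(name, 0.95), G, seed=args.seed)
        Gs = G.take_samples(sp.truth.sample_indices)
        write_truth_sidecar(sp, out / f"{name}.truth.json")
        results = run_experiment(Gs, sp.y, models, n_trials=args.trials,
                                 seed=args.seed, phenotype_name=name,
                                 model_overrides=overrides)
        all_results.extend(results)
        imp_dir = out / "importances" / name
        imp_dir.mkdir(parents=True, exist_ok=True)
        for r in results:
            print(f"{name} {r.model_name}: v = {r.mean:.3f} +/- {r.sd:.3f}")
            for k, v in enumerate(r.fold_scores):
                rows.append({"phenotype": name, "model": r.model_name, "fold": k,
                             "v": v, "best_params": json.dumps(r.best_params[k])})
            for k, imp in enumerate(r.fold_importances):
                if imp is not None:
                    pd.DataFrame({"marker_id": Gs.marker_ids, "value": imp}).to_csv(
                        imp_dir / f"{r.model_name}_fold{k}.csv", index=False)

    pd.DataFrame(rows).to_csv(out / "fold_results.csv", index=False)
    paths = results_heatmap(all_results, out / "heatmap")
    print(f"wrote {paths}")


if __name__ == "__main__":
    main()
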