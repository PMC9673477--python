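"""Score fold-aggregated feature importances against simulated ground truth.

Consumes the outputs of 02_benchmark_models.py: for each phenotype and model
with stored per-fold importances, aggregates the top-1,000 (min-max
normalized, fold-averaged), applies the 1%-of-maximum filter, and reports the
number of important features, the background-SNP true positive rate, the
detected causal SNPs with their ranks, and the effect-size/importance Pearson
correlation.  Writes the summary table and scatter pairs under
results/importance/.

Run after 02:  python analysis/03_importance_recovery.py
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gsbench.importance import (aggregate_across_folds, effect_importance_correlation,
                                score_against_truth)
from gsbench.simulate import GroundTruth, read_truth_sidecar


def load_truth(path) -> GroundTruth:
    d = read_truth_sidecar(path)
    return GroundTruth(
        background_indices=np.asarray(d["background_indices"]),
        gamma=np.asarray(d["gamma"]),
        causal_indices=np.asarray(d["causal_indices"]),
        beta=np.asarray(d["beta"]),
        interaction=tuple(d["interaction"]) if d["interaction"] else None,
        u=np.asarray(d["u"]), epsilon=np.asarray(d["epsilon"]),
        sigma2=d["sigma2"], sample_indices=np.asarray(d["sample_indices"]),
        x_fixed=np.empty((0, 0)),
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--benchmark", default="results/benchmark")
    ap.add_argument("--top-k", type=int, default=1000)
    ap.add_argument("--out", default="results/importance")
    args = ap.parse_args()

    bench = Path(args.benchmark)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    summary, scatters = [], []
    for pheno_dir in sorted((bench / "importances").iterdir()):
        truth = load_truth(bench / f"{pheno_dir.name}.truth.json")
        models = sorted({f.name.rsplit("_fold", 1)[0] for f in pheno_dir.glob("*_fold*.csv")})
        for name in models:
            vecs = [pd.read_csv(f)["value"].to_numpy()
                    for f in sorted(pheno_dir.glob(f"{name}_fold*.csv"))]
            avg = aggregate_across_folds(vecs, k=args.top_k)
            rep = score_against_truth(avg, truth, model_name=name)
            r = None
            try:
                r, table = effect_importance_correlation(truth, avg)
                table.insert(0, "model", name)
                table.insert(0, "phenotype", pheno_dir.name)
                scatters.append(table)
            except ValueError:
                pass
            summary.append({
                "phenotype": pheno_dir.name, "model": name,
                "n_important": rep.n_important,
                "n_important_filtered": rep.n_important_filtered,
                "background_found": rep.background_found,
                "tpr": round(rep.tpr, 3), "tpr_filtered": round(rep.tpr_filtered, 3),
                "causal_found": f"{rep.causal_found}/{rep.causal_total}",
                "causal_ranks": json.dumps(rep.causal_ranks[:10]),
                "pearson_r": None if r is None else round(r, 3),
            })
            print(f"{pheno_dir.name} {name}: {summary[-1]}")

    pd.DataFrame(summary).to_csv(out / "importance_summary.csv", index=False)
    if scatters:
        pd.concat(scatters).to_csv(out / "effect_scatter.csv", index=False)
    print(f"wrote {out / 'importance_summary.csv'}")


if __name__ == "__main__":
    main()
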