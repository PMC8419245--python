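"""Progression prediction: subset search with GLMM and LSSVM, IO vs IVUS.

Builds per-slice feature records (baseline predictors, ΔMinCapT benchmark
from IO follow-up), then runs the 5-fold CV predictor-subset search for
each method and arm.  By default a reduced 127-subset search over 7
predictors is run; ``--full`` enumerates all 511 subsets of the 9
predictors (slow, particularly for LSSVM).

Run after 03:  python analysis/04_predict_progression.py [--full]
"""

import argparse
import logging
import time
from pathlib import Path

import pandas as pd

from capmech.pipeline import CohortResults, build_feature_records
from capmech.prediction import PREDICTOR_NAMES, run_combination_search

logging.basicConfig(level=logging.WARNING)

OUT = Path("results")
REDUCED = ("LA", "PA", "PB", "MinCapT", "MeanCapT", "MeanCapS", "MaxCapSn")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--full", action="store_true", help="search all 511 subsets of 9 predictors")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--methods", nargs="+", default=["glmm", "lssvm"])
    args = ap.parse_args()

    features = pd.read_csv(OUT / "mechanics_features.csv",
                           dtype={"patient_id": str, "slice_id": str})
    results = CohortResults(features, {}, pd.DataFrame())
    predictors = PREDICTOR_NAMES if args.full else REDUCED

    for arm in ("IO", "IVUS"):
        records = build_feature_records(results, arm=arm)
        print(f"\n=== {arm} arm: {len(records)} records, "
              f"{(records.label == 1).sum()} progressive ===")
        for method in args.methods:
            t0 = time.time()
            report = run_combination_search(
                records, method, predictors=predictors, seed=args.seed
            )
            path = OUT / f"prediction_{method}_{arm.lower()}.csv"
            report.to_csv(path)
            best = report.iloc[0]
            singles = report[report.n_predictors == 1]
            print(f"{method}: best {best['subset']} "
                  f"Acc={best['Acc']:.3f} AUC={best['AUC']:.3f} "
                  f"| best single {singles.iloc[0]['subset']} "
                  f"AUC={singles.iloc[0]['AUC']:.3f} "
                  f"({time.time() - t0:.0f}s) -> {path.name}")


if __name__ == "__main__":
    main()
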