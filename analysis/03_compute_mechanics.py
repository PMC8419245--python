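"""Thin-layer FE cap stress/strain for every baseline slice, both arms.

For each baseline slice and modality (IO and IVUS), calibrates the
circumferential preshrink at the patient's diastolic pressure, solves the
modified Mooney–Rivlin inflation problem, and extracts cap stress/strain
aggregates (MaxCapS, MeanCapS, MaxCapSn, MeanCapSn).

This is the expensive stage (a few seconds per slice-model).

Run after 01:  python analysis/03_compute_mechanics.py [--density 0.5]
"""

import argparse
import logging
import time
from pathlib import Path

from capmech.cli import _load_cohort_dir
from capmech.pipeline import MechanicsConfig, analyze_cohort, patient_level_table

logging.basicConfig(level=logging.INFO)

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--density", type=float, default=0.5, help="mesh density scale")
    ap.add_argument("--pressure", choices=["diastolic", "systolic"], default="diastolic")
    args = ap.parse_args()

    cohort = _load_cohort_dir(COHORT)
    t0 = time.time()
    results = analyze_cohort(
        cohort,
        mechanics=True,
        config=MechanicsConfig(eval_pressure=args.pressure, mesh_density=args.density),
    )
    results.features.to_csv(OUT / "mechanics_features.csv", index=False, float_format="%.6f")
    patients = patient_level_table(results)
    patients.to_csv(OUT / "patient_mechanics.csv", index=False, float_format="%.6f")

    base = results.features[results.features.timepoint == "baseline"]
    n_fail = int(base["MaxCapS"].isna().sum())
    print(f"solved {len(base)} baseline slice-models in {time.time() - t0:.0f}s "
          f"({n_fail} failures)")
    print(base.groupby("modality")[["MinCapT", "MeanCapS", "MaxCapS", "MeanCapSn", "MaxCapSn"]]
          .mean().round(3).to_string())
    print("-> results/mechanics_features.csv, results/patient_mechanics.csv")


if __name__ == "__main__":
    main()
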