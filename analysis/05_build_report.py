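"""Assemble the publication-style tables.

Produces, from the simulated cohort's patient-level aggregates, the
IVUS-vs-IO error tables (cap thickness, cap stress, cap strain, with
Max/Min/Mean ± SD rows) and, from the prediction reports, the
morphology-only vs morphology+mechanics comparison.  Every table is
written with a hash-linked provenance manifest.

Run after 03 (and optionally 04):  python analysis/05_build_report.py
"""

import logging
from pathlib import Path

import pandas as pd

from capmech.report import error_tables, morphology_vs_combined, write_table

logging.basicConfig(level=logging.INFO)

OUT = Path("results/tables")
RES = Path("results")


def main() -> None:
    patients = pd.read_csv(RES / "patient_mechanics.csv", dtype={"patient_id": str})
    io_p = patients[patients.modality == "IO"]
    iv_p = patients[patients.modality == "IVUS"]
    inputs = [RES / "patient_mechanics.csv"]
    for name, table in error_tables(io_p, iv_p).items():
        path = write_table(table, OUT / f"error_{name}.csv", inputs=inputs, markdown=True)
        print(f"wrote {path}")
        summary = table.iloc[-1]
        err_cols = [c for c in table.columns if c.endswith("_error_pct")]
        print("   Mean ± SD:", {c: summary[c] for c in err_cols})

    for report_path in sorted(RES.glob("prediction_*_io.csv")):
        rep = pd.read_csv(report_path)
        cmp = morphology_vs_combined(rep)
        path = write_table(
            cmp, OUT / f"morpho_vs_combined_{report_path.stem.split('_')[1]}.csv",
            inputs=[report_path],
        )
        print(f"wrote {path}")
        print(cmp.to_string(index=False))


if __name__ == "__main__":
    main()
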