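"""Publication-style tables: IVUS-vs-IO error summaries and prediction reports.

Every emitted table is written as CSV (and optionally Markdown) together
with a JSON manifest recording the configuration, seeds, package version,
and SHA-256 hashes of the upstream artifacts it was derived from, so each
number is traceable to a logged input.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from capmech.geometry import percent_error, summarize
from capmech.prediction import MORPHOLOGY_PREDICTORS

# rounding conventions: mm and strain to 3 decimals, kPa and percent to 2
ROUNDING = {"mm": 3, "strain": 3, "kPa": 2, "percent": 2}

QUANTITY_UNITS = {
    "MinCapT": "mm",
    "MeanCapT": "mm",
    "MeanCapS": "kPa",
    "MaxCapS": "kPa",
    "MeanCapSn": "strain",
    "MaxCapSn": "strain",
}


def error_table(
    io_patient: pd.DataFrame, ivus_patient: pd.DataFrame, quantities: tuple[str, str]
) -> pd.DataFrame:
    """Per-patient IO / IVUS / Error(%) columns plus Max/Min/Mean±SD rows.

    ``io_patient`` / ``ivus_patient`` are patient-level aggregate tables
    with a ``patient_id`` column; patients missing from either arm are
    excluded (logged via the manifest row count).
    """
    io = io_patient.set_index("patient_id")
    iv = ivus_patient.set_index("patient_id")
    common = [p for p in io.index if p in iv.index]
    rows = []
    for pid in common:
        row = {"patient": pid}
        for q in quantities:
            a, b = float(io.loc[pid, q]), float(iv.loc[pid, q])
            nd = ROUNDING[QUANTITY_UNITS[q]]
            row[f"{q}_io"] = round(a, nd)
            row[f"{q}_ivus"] = round(b, nd)
            row[f"{q}_error_pct"] = round(percent_error(a, b), 2)
        rows.append(row)
    table = pd.DataFrame(rows)

    summary_rows = []
    for stat in ("Max", "Min", "Mean ± SD"):
        summary_rows.append({"patient": stat})
    for q in quantities:
        for col, nd in (
            (f"{q}_io", ROUNDING[QUANTITY_UNITS[q]]),
            (f"{q}_ivus", ROUNDING[QUANTITY_UNITS[q]]),
            (f"{q}_error_pct", 2),
        ):
            mx, mn, mean, sd = summarize(table[col])
            summary_rows[0][col] = round(mx, nd)
            summary_rows[1][col] = round(mn, nd)
            summary_rows[2][col] = f"{mean:.2f} ± {sd:.2f}"
    return pd.concat([table, pd.DataFrame(summary_rows)], ignore_index=True)


def error_tables(io_patient: pd.DataFrame, ivus_patient: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The three error tables: cap thickness, cap stress, cap strain."""
    return {
        "cap_thickness": error_table(io_patient, ivus_patient, ("MinCapT", "MeanCapT")),
        "cap_stress": error_table(io_patient, ivus_patient, ("MeanCapS", "MaxCapS")),
        "cap_strain": error_table(io_patient, ivus_patient, ("MeanCapSn", "MaxCapSn")),
    }


def morphology_vs_combined(report: pd.DataFrame) -> pd.DataFrame:
    """Best morphology-only subset vs best overall subset, side by side.

    Morphology-only candidates are the 31 subsets of the five
    morphological predictors; the overall pool is every subset in the
    report.  Ranking is AUC first, accuracy as tiebreak.
    """
    morpho = set(MORPHOLOGY_PREDICTORS)
    ok = report.dropna(subset=["AUC"])
    is_morpho = ok["subset"].map(lambda s: set(s.split("+")).issubset(morpho))
    ranked = ok.sort_values(["AUC", "Acc"], ascending=False, kind="mergesort")
    best_overall = ranked.iloc[0]
    best_morpho = ranked[is_morpho.loc[ranked.index]].iloc[0]
    out = pd.DataFrame([best_morpho, best_overall])
    out.insert(0, "pool", ["morphology-only", "morphology+mechanics"])
    return out[["pool", "subset", "Acc", "Sen", "Spe", "AUC"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# provenance


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    inputs: list[str | Path] | None = None,
    config=None,
    markdown: bool = False,
) -> Path:
    """Write a table with a hash-linked provenance manifest alongside it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if markdown:
        path.with_suffix(".md").write_text(df.to_markdown(index=False) + "\n")
    from capmech import __version__

    manifest = {
        "written": datetime.now(timezone.utc).isoformat(),
        "capmech_version": __version__,
        "python": platform.python_version(),
        "table": path.name,
        "table_sha256": _sha256(path),
        "inputs": {str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()},
        "config": asdict(config) if is_dataclass(config) else config,
    }
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
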