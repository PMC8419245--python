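"""Patient-level validation data from a nine-patient IVUS+OCT follow-up study.

A published nine-patient coronary follow-up study reported patient-level
fibrous-cap thickness, cap stress, and cap strain aggregates from 114
matched lipid slices, for both fused IVUS+OCT (IO, gold standard) and
IVUS-only cross sections, together with IVUS-vs-IO percent errors.  Those
printed per-patient values are shipped here as a small validation dataset:
the error-arithmetic and summary routines in :mod:`capmech.geometry` must
reproduce every printed error cell and summary row from the printed inputs.

All thicknesses are in mm, stresses in kPa, strains dimensionless, errors
in percent.

One published cell is internally inconsistent: Patient 4's MeanCapT error
is printed as −5.86%, but its own printed inputs (0.536 → 0.451 mm) give
−15.86%, and the table's printed Mean ± SD row (0.16 ± 20.86) is only
reproduced with −15.86%.  The printed value is kept in the table as-is;
``KNOWN_INCONSISTENT_CELLS`` records the implied correction.
"""

from __future__ import annotations

import pandas as pd

_PATIENTS = [f"Patient {i}" for i in range(1, 10)]

# Minimum / mean fibrous-cap thickness (mm) per patient, IO vs IVUS,
# with the printed IVUS-vs-IO percent error.
_CAP_THICKNESS_ROWS = [
    # MinCapT: IO, IVUS, Err%   MeanCapT: IO, IVUS, Err%
    (0.162, 0.195, 20.37, 0.251, 0.315, 25.50),
    (0.242, 0.190, -21.49, 0.385, 0.379, -1.56),
    (0.271, 0.284, 4.80, 0.390, 0.447, 14.62),
    (0.317, 0.135, -57.41, 0.536, 0.451, -5.86),
    (0.222, 0.093, -58.11, 0.376, 0.262, -30.32),
    (0.324, 0.141, -56.48, 0.602, 0.499, -17.11),
    (0.181, 0.144, -20.44, 0.325, 0.382, 17.54),
    (0.127, 0.124, -2.36, 0.273, 0.230, -15.75),
    (0.228, 0.239, 4.82, 0.348, 0.433, 24.43),
]

# Mean / maximum cap stress (kPa).
_CAP_STRESS_ROWS = [
    # MeanCapS: IO, IVUS, Err%   MaxCapS: IO, IVUS, Err%
    (71.77, 44.73, -37.68, 78.65, 54.74, -30.40),
    (70.76, 71.53, 1.09, 82.14, 81.29, -1.03),
    (90.49, 91.83, 1.48, 101.82, 100.95, -0.85),
    (48.77, 70.35, 44.25, 73.47, 107.39, 46.17),
    (71.89, 95.88, 33.37, 95.45, 113.03, 18.42),
    (69.64, 82.94, 19.10, 97.99, 106.47, 8.65),
    (85.58, 68.24, -20.26, 112.25, 78.89, -29.72),
    (60.91, 86.09, 41.34, 68.01, 94.19, 38.49),
    (34.58, 49.34, 42.68, 49.43, 57.08, 15.48),
]

# Mean / maximum cap strain (dimensionless).
_CAP_STRAIN_ROWS = [
    # MeanCapSn: IO, IVUS, Err%   MaxCapSn: IO, IVUS, Err%
    (0.144, 0.111, -22.92, 0.154, 0.125, -18.83),
    (0.189, 0.176, -6.88, 0.215, 0.192, -10.70),
    (0.175, 0.177, 1.14, 0.191, 0.190, -0.52),
    (0.149, 0.172, 15.44, 0.202, 0.217, 7.43),
    (0.065, 0.073, 12.31, 0.084, 0.094, 11.90),
    (0.177, 0.185, 4.52, 0.211, 0.212, 0.47),
    (0.169, 0.151, -10.65, 0.201, 0.161, -19.90),
    (0.159, 0.185, 16.35, 0.171, 0.194, 13.45),
    (0.108, 0.140, 29.63, 0.136, 0.160, 17.65),
]

# (table, quantity, patient) -> error implied by the printed inputs, where
# the printed error cell contradicts both the inputs and the summary row
KNOWN_INCONSISTENT_CELLS = {("cap_thickness", "MeanCapT", "Patient 4"): -15.86}

# Printed summary rows (mean ± sample SD of the nine per-patient errors).
PRINTED_ERROR_SUMMARY = {
    "MinCapT": (-20.70, 30.32),
    "MeanCapT": (0.16, 20.86),
    "MeanCapS": (13.93, 29.69),
    "MaxCapS": (7.24, 26.47),
    "MeanCapSn": (4.33, 16.10),
    "MaxCapSn": (0.11, 13.94),
}

# Printed column means (IO, IVUS) of the cap-thickness table.
PRINTED_COLUMN_MEANS = {
    "MinCapT": (0.23, 0.17),
    "MeanCapT": (0.39, 0.38),
}

# Per-patient diastolic–systolic blood pressure ranges (mmHg) of the cohort.
PATIENT_PRESSURES_MMHG = {
    "P1": (71, 138),
    "P2": (84, 155),
    "P3": (63, 149),
    "P4": (66, 150),
    "P5": (55, 150),
    "P6": (62, 151),
    "P7": (79, 117),
    "P8": (78, 128),
    "P9": (80, 143),
}


def _build(rows, left: str, right: str) -> pd.DataFrame:
    rec = []
    for patient, row in zip(_PATIENTS, rows):
        rec.append(
            {
                "patient": patient,
                f"{left}_io": row[0],
                f"{left}_ivus": row[1],
                f"{left}_error_pct": row[2],
                f"{right}_io": row[3],
                f"{right}_ivus": row[4],
                f"{right}_error_pct": row[5],
            }
        )
    return pd.DataFrame.from_records(rec)


def cap_thickness_table() -> pd.DataFrame:
    """Per-patient MinCapT / MeanCapT (mm) for IO and IVUS with printed errors."""
    return _build(_CAP_THICKNESS_ROWS, "MinCapT", "MeanCapT")


def cap_stress_table() -> pd.DataFrame:
    """Per-patient MeanCapS / MaxCapS (kPa) for IO and IVUS with printed errors."""
    return _build(_CAP_STRESS_ROWS, "MeanCapS", "MaxCapS")


def cap_strain_table() -> pd.DataFrame:
    """Per-patient MeanCapSn / MaxCapSn for IO and IVUS with printed errors."""
    return _build(_CAP_STRAIN_ROWS, "MeanCapSn", "MaxCapSn")


def all_error_tables() -> dict[str, pd.DataFrame]:
    """All three validation tables keyed by quantity pair."""
    return {
        "cap_thickness": cap_thickness_table(),
        "cap_stress": cap_stress_table(),
        "cap_strain": cap_strain_table(),
    }
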