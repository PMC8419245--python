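"""End-to-end orchestration: contours → geometry → mechanics → records.

Ties the stages together for a whole cohort: cap profiles and morphology
per slice and modality, preshrink calibration plus thin-layer inflation for
baseline mechanics, patient-level pooling for the error tables, and the
feature records consumed by the progression classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from capmech.cohort import Cohort, MMHG_TO_KPA
from capmech.contours import ContourSet
from capmech.femesh import build_mesh
from capmech.geometry import build_cap_profile, morpho_features, pool_cap_values
from capmech.materials import MaterialParams
from capmech.prediction import PREDICTOR_NAMES, make_records
from capmech.preshrink import apply_shrink, calibrate_shrink
from capmech.solver import ThinLayerModel, cap_aggregates, stress_strain_fields

logger = logging.getLogger(__name__)


@dataclass
class MechanicsConfig:
    """Knobs of the per-slice mechanics stage."""

    eval_pressure: str = "diastolic"  # or "systolic"
    axial_stretch: float = 1.05
    mesh_density: float = 0.5
    calibrate: bool = True
    materials: dict[str, MaterialParams] | None = None


@dataclass
class CohortResults:
    """Per-slice feature table plus pooled per-patient cap point values."""

    features: pd.DataFrame
    pooled: dict  # (patient_id, modality) -> {"cap": [...], "stress": [...], "strain": [...]}
    pressures: pd.DataFrame


@dataclass
class SliceMechanics:
    aggregates: object  # CapAggregates or None
    circ_shrink: float
    stress_points: np.ndarray
    strain_points: np.ndarray
    displacement: np.ndarray | None = None


def slice_mechanics(
    contours: ContourSet,
    pressure_kpa: float,
    profile=None,
    config: MechanicsConfig | None = None,
    shrink_initial: float | None = None,
    u_initial: np.ndarray | None = None,
) -> SliceMechanics:
    """Preshrink, inflate, and aggregate cap stress/strain for one slice.

    ``shrink_initial`` / ``u_initial`` warm-start the calibration with the
    factor and displacement field of a previously solved slice (the
    structured mesh topology is shared at fixed density).
    """
    config = config or MechanicsConfig()
    if profile is None:
        profile = build_cap_profile(contours)
    model = u = None
    shrink = 1.0
    if config.calibrate and pressure_kpa > 0:
        cal = calibrate_shrink(
            contours,
            pressure_kpa,
            axial_stretch=config.axial_stretch,
            materials=config.materials,
            mesh_density=config.mesh_density,
            initial=shrink_initial,
            u0=u_initial,
        )
        shrink = cal.circ_shrink
        # the calibration's last evaluation is the solve at the returned factor
        model, u = cal.model, cal.displacement
    if model is None:
        shrunk = (
            apply_shrink(contours, shrink, config.axial_stretch)
            if shrink != 1.0
            else contours
        )
        mesh = build_mesh(shrunk, target_density=config.mesh_density)
        model = ThinLayerModel(mesh, config.materials, axial_stretch=config.axial_stretch)
        u = model.solve(pressure_kpa, u0=u_initial)
    result = stress_strain_fields(model, u, pressure_kpa)
    agg = cap_aggregates(result, profile)
    s_pts, e_pts = (
        getattr(agg, "_points", (np.empty(0), np.empty(0)))
        if agg is not None
        else (np.empty(0), np.empty(0))
    )
    return SliceMechanics(agg, shrink, s_pts, e_pts, u)


def analyze_cohort(
    cohort: Cohort,
    mechanics: bool = True,
    config: MechanicsConfig | None = None,
    modalities=("IO", "IVUS"),
) -> CohortResults:
    """Geometry (both timepoints) and baseline mechanics for every slice.

    Baseline mechanics runs per modality at the patient's evaluation
    pressure (diastolic by default); the preshrink factor calibrated for a
    patient's previous slice warm-starts the next calibration.
    """
    config = config or MechanicsConfig()
    p_col = "diastolic_mmHg" if config.eval_pressure == "diastolic" else "systolic_mmHg"
    pressures = cohort.pressures.set_index("patient_id")[p_col]

    rows = []
    pooled: dict = {}
    shrink_warm: dict = {}
    for cs_slice in cohort.slices:
        p_kpa = float(pressures.loc[cs_slice.patient_id]) * MMHG_TO_KPA
        for (timepoint, modality), cs in cs_slice.sets.items():
            if modality not in modalities:
                continue
            profile = build_cap_profile(cs)
            feats = morpho_features(cs, profile)
            row = {
                "patient_id": cs_slice.patient_id,
                "slice_id": cs_slice.slice_id,
                "timepoint": timepoint,
                "modality": modality,
                "LA": feats.LA,
                "PA": feats.PA,
                "PB": feats.PB,
                "MinCapT": feats.MinCapT,
                "MeanCapT": feats.MeanCapT,
            }
            key = (cs_slice.patient_id, modality)
            store = pooled.setdefault(key, {"cap": [], "stress": [], "strain": []})
            if timepoint == "baseline" and feats.has_cap:
                store["cap"].append(profile.cap_values)
            if mechanics and timepoint == "baseline":
                warm = shrink_warm.get(modality, {})
                try:
                    mech = slice_mechanics(
                        cs,
                        p_kpa,
                        profile=profile,
                        config=config,
                        shrink_initial=warm.get("shrink"),
                        u_initial=warm.get("u"),
                    )
                except Exception as exc:
                    logger.warning(
                        "mechanics failed for %s/%s %s: %s",
                        cs_slice.patient_id,
                        cs_slice.slice_id,
                        modality,
                        exc,
                    )
                    mech = None
                if mech is not None and mech.aggregates is not None:
                    row.update(mech.aggregates.as_dict())
                    store["stress"].append(mech.stress_points)
                    store["strain"].append(mech.strain_points)
                row["circ_shrink"] = mech.circ_shrink if mech else np.nan
                if mech is not None:
                    shrink_warm[modality] = {"shrink": mech.circ_shrink, "u": mech.displacement}
            rows.append(row)
    return CohortResults(pd.DataFrame(rows), pooled, cohort.pressures)


def patient_level_table(results: CohortResults) -> pd.DataFrame:
    """Patient-level aggregates pooled over all lipid slices of a patient.

    MinCapT is the minimum over all cap point thicknesses of all the
    patient's lipid slices (MeanCapT the mean); stress/strain aggregates
    pool the per-point cap values the same way.
    """
    rows = []
    for (pid, modality), store in sorted(results.pooled.items()):
        caps = pool_cap_values(store["cap"])
        stresses = pool_cap_values(store["stress"])
        strains = pool_cap_values(store["strain"])
        rows.append(
            {
                "patient_id": pid,
                "modality": modality,
                "MinCapT": float(caps.min()) if caps.size else np.nan,
                "MeanCapT": float(caps.mean()) if caps.size else np.nan,
                "MeanCapS": float(stresses.mean()) if stresses.size else np.nan,
                "MaxCapS": float(stresses.max()) if stresses.size else np.nan,
                "MeanCapSn": float(strains.mean()) if strains.size else np.nan,
                "MaxCapSn": float(strains.max()) if strains.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def build_feature_records(results: CohortResults, arm: str = "IO") -> pd.DataFrame:
    """FeatureRecords for one experiment arm.

    Predictors come from the arm's baseline slices; ΔMinCapT (and hence the
    label) always comes from the IO baseline/follow-up MinCapT benchmark.
    """
    f = results.features
    base_arm = f[(f.timepoint == "baseline") & (f.modality == arm)].copy()
    base_io = f[(f.timepoint == "baseline") & (f.modality == "IO")]
    fu_io = f[(f.timepoint == "follow_up") & (f.modality == "IO")]
    io_min = base_io.set_index(["patient_id", "slice_id"])["MinCapT"]
    base_arm["MinCapT_io"] = [
        io_min.get((r.patient_id, r.slice_id), np.nan) for r in base_arm.itertuples()
    ]
    fu = fu_io[["patient_id", "slice_id", "MinCapT"]].rename(columns={"MinCapT": "MinCapT_io"})
    predictors = [p for p in PREDICTOR_NAMES if p in base_arm.columns]
    return make_records(base_arm, fu, tuple(predictors))
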