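"""Synthetic cohort of matched baseline/follow-up, IO/IVUS plaque contours.

Patient IVUS+OCT follow-up data of the kind this pipeline analyses are not
publicly deposited, so this module generates a cohort with the statistical
structure the analysis assumes:

* ellipse-like vessel cross-sections with low-order Fourier perturbation of
  the lumen radius and an eccentric wall, at coronary scale (lumen radius
  ≈ 1.5 mm, wall ≈ 1 mm);
* a lipid crescent under a fibrous cap over a random angular arc, with slice
  minimum cap thickness in the thin-cap range observed clinically;
* an IVUS arm derived from the gold-standard IO arm by a patient-level
  multiplicative bias on cap thickness plus pointwise noise and a
  resolution-related quantization — emulating the 150–200 µm IVUS
  resolution limit that motivates fused IO imaging (lumen and outwall are
  shared between modalities; only the cap differs);
* a planted progression signal: the cap-thickness change ΔMinCapT is a
  linear model in standardized baseline (PA, MinCapT, PB) and a cap-stress
  proxy — the Laplace estimate (pressure × lumen radius / cap thickness)
  times a lipid-burden factor — standing in for the FE-computed mean cap
  stress the generator cannot itself run.

Fixed seed ⇒ byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from capmech.contours import ContourSet, SliceContour, validate_contour_set
from capmech.geometry import area_centroid, polygon_area

logger = logging.getLogger(__name__)

MMHG_TO_KPA = 0.133322

PLANTED_PREDICTORS = ("PA", "MinCapT", "MeanCapS", "PB")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the nine-patient, ~114-lipid-slice study scale: 9
    patients × 12–14 slices, patient-level IVUS cap-thickness bias drawn so
    per-patient MinCapT errors span roughly −58% to +20%, and a progression
    signal planted on (PA, MinCapT, cap-stress proxy, PB).
    """

    n_patients: int = 9
    slices_per_patient: tuple[int, int] = (12, 14)
    seed: int = 0
    lumen_radius_mm: tuple[float, float] = (1.5, 0.25)  # mean, sd
    wall_thickness_mm: tuple[float, float] = (1.0, 0.15)  # mean, sd
    fourier_perturbation: tuple[float, ...] = (0.08, 0.05, 0.03)  # modes 2,3,4 (mm)
    lipid_arc_deg: tuple[float, float] = (70.0, 160.0)
    cap_thickness_mm: tuple[float, float] = (0.10, 0.40)  # slice MinCapT range
    ivus_patient_bias_mean: float = -0.20
    ivus_patient_bias_sd: float = 0.30
    ivus_point_noise_sd_mm: float = 0.015
    ivus_resolution_floor_mm: float = 0.15
    # planted ΔMinCapT effect (mm per SD) on standardized (PA, MinCapT, MeanCapS, PB).
    # weights are allocated proportionally to each predictor's √VIF in the
    # generated design (the stress proxy is strongly collinear with MinCapT,
    # PB mildly with PA), so all four factors carry comparable *unique* signal
    progression_coefficients: tuple[float, float, float, float] = (-0.025, 0.045, -0.048, -0.026)
    progression_intercept_mm: float = 0.0  # class-balance knob
    progression_noise_sd_mm: float = 0.025
    pressure_mmHg: tuple[tuple[float, float], tuple[float, float]] = ((55.0, 90.0), (117.0, 155.0))

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        lo, hi = self.slices_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("invalid slices_per_patient range")
        for name in ("lumen_radius_mm", "wall_thickness_mm"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} must have positive mean and non-negative sd")
        if not (0 < self.lipid_arc_deg[0] <= self.lipid_arc_deg[1] < 360):
            raise ValueError("lipid arc must lie within (0, 360) degrees")
        if not (0 < self.cap_thickness_mm[0] <= self.cap_thickness_mm[1]):
            raise ValueError("cap thickness range must be positive")
        if self.ivus_resolution_floor_mm < 0 or self.ivus_point_noise_sd_mm < 0:
            raise ValueError("IVUS degradation scales must be non-negative")
        (dlo, dhi), (slo, shi) = self.pressure_mmHg
        if not (0 < dlo <= dhi < slo <= shi):
            raise ValueError("diastolic range must be positive and below the systolic range")
        if self.progression_noise_sd_mm < 0:
            raise ValueError("progression noise sd must be non-negative")


@dataclass
class CohortSlice:
    """All four matched contour sets of one (patient, slice)."""

    patient_id: str
    slice_id: str
    sets: dict  # (timepoint, modality) -> ContourSet


@dataclass
class Cohort:
    config: CohortConfig
    slices: list[CohortSlice]
    ground_truth: pd.DataFrame  # patient_id, slice_id, planted_delta_mincapt_mm, patient_bias
    pressures: pd.DataFrame  # patient_id, diastolic_mmHg, systolic_mmHg

    def contour_sets(self) -> list[ContourSet]:
        out = []
        for s in self.slices:
            out.extend(s.sets.values())
        return out


# ---------------------------------------------------------------------------
# geometric construction


def _radius_function(rng: np.random.Generator, r0: float, amplitudes) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients (amplitude, phase) per Fourier mode 2..m+1."""
    amps = np.array([a * rng.uniform(0.3, 1.0) for a in amplitudes])
    phases = rng.uniform(0, 2 * np.pi, size=len(amps))
    return amps, phases


def _eval_radius(theta: np.ndarray, r0: float, amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    r = np.full_like(theta, r0, dtype=float)
    for m, (a, p) in enumerate(zip(amps, phases), start=2):
        r = r + a * np.cos(m * theta + p)
    return r


@dataclass
class _SliceRecipe:
    """Parametric description of one baseline IO slice (internal)."""

    r0: float
    amps: np.ndarray
    phases: np.ndarray
    t0: float
    ecc: float
    theta_p: float  # thick-wall / lipid-center direction
    arc: float  # lipid angular width (rad)
    cap_min: float
    cap_edge: float
    cap_shape: float  # exponent of the cap-thickness rise toward the arc ends
    lipid_depth: float

    def lumen_radius(self, theta: np.ndarray) -> np.ndarray:
        return _eval_radius(theta, self.r0, self.amps, self.phases)

    def wall_thickness(self, theta: np.ndarray) -> np.ndarray:
        return self.t0 * (1.0 + self.ecc * np.cos(theta - self.theta_p))

    def cap_profile(self, theta: np.ndarray) -> np.ndarray:
        """Cap thickness over the lipid arc (radial distance lumen → lipid)."""
        rel = np.abs(np.angle(np.exp(1j * (theta - self.theta_p)))) / (self.arc / 2.0)
        return self.cap_min + (self.cap_edge - self.cap_min) * rel**self.cap_shape

    def lipid_thickness(self, theta: np.ndarray) -> np.ndarray:
        rel = np.abs(np.angle(np.exp(1j * (theta - self.theta_p)))) / (self.arc / 2.0)
        return self.lipid_depth * np.clip(1.0 - rel**2, 0.0, None)


def _polygon_from_radius(theta: np.ndarray, radius: np.ndarray) -> np.ndarray:
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


def _build_lipid_polygon(recipe: _SliceRecipe, cap: np.ndarray | None = None, n_arc: int = 40) -> np.ndarray:
    """Crescent between cap inner edge and lipid outer edge over the arc."""
    half = recipe.arc / 2.0
    # trim the exact pinch points to keep the polygon simple
    rel = np.linspace(-0.985, 0.985, n_arc)
    theta = recipe.theta_p + rel * half
    rl = recipe.lumen_radius(theta)
    c = recipe.cap_profile(theta) if cap is None else cap
    d = np.maximum(recipe.lipid_thickness(theta), 0.02)
    t = recipe.wall_thickness(theta)
    inner = rl + np.minimum(c, 0.9 * t)
    outer = np.minimum(inner + d, rl + 0.92 * t)
    outer = np.maximum(outer, inner + 0.02)
    pts = np.vstack(
        [
            _polygon_from_radius(theta, inner),
            _polygon_from_radius(theta[::-1], outer[::-1]),
        ]
    )
    return pts


def _build_slice_sets(recipe: _SliceRecipe, delta: float, n_boundary: int = 72) -> dict:
    """Baseline and follow-up IO contour sets from one recipe.

    The follow-up slice displaces the lipid inner edge so the minimum cap
    thickness changes by ``delta`` (clipped to keep the geometry valid);
    lumen and outwall are unchanged.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_boundary, endpoint=False)
    rl = recipe.lumen_radius(theta)
    ro = rl + recipe.wall_thickness(theta)
    lumen = _polygon_from_radius(theta, rl)
    outwall = _polygon_from_radius(theta, ro)

    out = {}
    for timepoint in ("baseline", "follow_up"):
        if timepoint == "baseline":
            lipid = _build_lipid_polygon(recipe)
        else:
            half = recipe.arc / 2.0
            rel = np.linspace(-0.985, 0.985, 40)
            th = recipe.theta_p + rel * half
            cap = recipe.cap_profile(th) + delta
            cap = np.clip(cap, 0.02, None)
            lipid = _build_lipid_polygon(recipe, cap=cap)
        out[timepoint] = {"lumen": lumen, "outwall": outwall, "lipid": lipid}
    return out


# ---------------------------------------------------------------------------
# IVUS degradation


def _star_radii(poly_points: np.ndarray, center: np.ndarray, theta: float) -> list[float]:
    """Radii of all boundary crossings of the ray at angle theta."""
    ring = LineString(np.vstack([poly_points, poly_points[:1]]))
    reach = 10.0 * (np.abs(poly_points - center).max() + 1.0)
    ray = LineString(
        [center, center + reach * np.array([np.cos(theta), np.sin(theta)])]
    )
    hit = ring.intersection(ray)
    if hit.is_empty:
        return []
    pts = []
    if isinstance(hit, Point):
        pts = [hit]
    else:
        for g in getattr(hit, "geoms", [hit]):
            if isinstance(g, Point):
                pts.append(g)
            else:
                pts.extend(Point(c) for c in g.coords)
    c = Point(center)
    return sorted(p.distance(c) for p in pts)


def quantize_cap(cap: np.ndarray, floor_mm: float) -> np.ndarray:
    """Resolution-related quantization of cap thickness.

    Values are rounded to multiples of half the resolution floor with a
    one-step minimum; a zero floor disables quantization.
    """
    if floor_mm <= 0:
        return cap
    step = floor_mm / 2.0
    return np.maximum(step, np.round(np.asarray(cap, float) / step) * step)


def degrade_to_ivus(
    io_set: ContourSet,
    patient_bias: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> ContourSet:
    """Derive the IVUS-arm contour set from a gold-standard IO set.

    Lumen and outwall are carried over unchanged (the fused IO slice takes
    its outwall from IVUS, so only the cap measurement differs between
    modalities).  The lipid *inner* boundary is displaced radially about
    the lumen centroid: cap thickness is scaled by ``1 + patient_bias``,
    perturbed pointwise, then quantized at the resolution floor.  Inner
    displacement is clipped so the lipid stays inside the wall annulus.
    """
    if "lumen" not in io_set or "outwall" not in io_set:
        raise ValueError("IO set must contain lumen and outwall")
    rng = rng if rng is not None else np.random.default_rng(0)

    out: ContourSet = {}
    for role, contour in io_set.items():
        if role != "lipid":
            out[role] = SliceContour(
                contour.patient_id,
                contour.slice_id,
                contour.timepoint,
                "IVUS",
                role,
                contour.points.copy(),
            )
    if "lipid" not in io_set:
        return out

    lumen_pts = io_set["lumen"].points
    center = area_centroid(lumen_pts)
    lipid = io_set["lipid"]
    new_pts = lipid.points.copy()
    n = len(new_pts)
    noise = (
        rng.normal(0.0, config.ivus_point_noise_sd_mm, size=n)
        if config.ivus_point_noise_sd_mm > 0
        else np.zeros(n)
    )
    for i, v in enumerate(lipid.points):
        d = v - center
        theta = float(np.arctan2(d[1], d[0]))
        r_v = float(np.hypot(*d))
        lum_hits = _star_radii(lumen_pts, center, theta)
        lip_hits = _star_radii(lipid.points, center, theta)
        if not lum_hits or len(lip_hits) < 2:
            continue
        r_l = lum_hits[0]
        r_in, r_out = lip_hits[0], lip_hits[-1]
        # only inner-edge vertices move
        if abs(r_v - r_in) > abs(r_v - r_out):
            continue
        cap = r_v - r_l
        if cap <= 0:
            continue
        cap_new = cap * (1.0 + patient_bias) + noise[i]
        cap_new = float(quantize_cap(np.array([max(cap_new, 1e-3)]), config.ivus_resolution_floor_mm)[0])
        # clip so the lipid stays within the wall annulus / below its outer edge
        cap_new = min(max(cap_new, 0.02), max(r_out - r_l - 0.02, 0.02))
        new_pts[i] = center + (r_l + cap_new) * np.array([np.cos(theta), np.sin(theta)])
    lipid_poly = Polygon(new_pts)
    if not lipid_poly.is_valid:
        # fall back to the noise-free displacement if noise broke simplicity
        return degrade_to_ivus(
            io_set,
            patient_bias,
            CohortConfig(**{**config.__dict__, "ivus_point_noise_sd_mm": 0.0}),
            rng,
        )
    out["lipid"] = SliceContour(
        lipid.patient_id, lipid.slice_id, lipid.timepoint, "IVUS", "lipid", new_pts
    )
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _draw_recipe(rng: np.random.Generator, config: CohortConfig) -> _SliceRecipe | None:
    """One slice draw; None when the draw has no room for a lipid core."""
    r0 = max(0.8, rng.normal(*config.lumen_radius_mm))
    t0 = max(0.5, rng.normal(*config.wall_thickness_mm))
    amps, phases = _radius_function(rng, r0, config.fourier_perturbation)
    ecc = rng.uniform(0.05, 0.3)
    theta_p = rng.uniform(0, 2 * np.pi)
    arc = np.deg2rad(rng.uniform(*config.lipid_arc_deg))
    cap_min = rng.uniform(*config.cap_thickness_mm)
    # wide, shape-varying rise toward the arc ends decouples the mean cap
    # thickness from the minimum, as in segmented patient slices
    cap_edge = cap_min + rng.uniform(0.10, 0.55)
    cap_shape = rng.uniform(1.0, 3.0)
    max_depth = 0.88 * t0 * (1.0 - ecc) - cap_min - 0.05
    if max_depth < 0.15:  # lipid would be thicker than the wall allows
        return None
    lipid_depth = rng.uniform(0.5, 1.0) * max_depth
    return _SliceRecipe(
        r0, amps, phases, t0, ecc, theta_p, arc, cap_min, cap_edge, cap_shape, lipid_depth
    )


def _recipe_predictors(recipe: _SliceRecipe, p_dia_kpa: float) -> np.ndarray:
    """Planted-signal predictors (PA, MinCapT, cap-stress proxy, PB).

    The stress proxy is the Laplace estimate p·r/h augmented by a
    lipid-burden factor: a deeper/wider soft pool transfers more load to
    the cap.  The factor's sensitivities (≈1.0 per unit depth/wall ratio,
    ≈0.35 per unit arc fraction) match the thin-layer FE response, and —
    unlike the Laplace part — they vary independently of every
    morphological predictor, so this share of the planted signal is
    attributable only through the computed cap stress.
    """
    theta = np.linspace(0.0, 2 * np.pi, 144, endpoint=False)
    rl = recipe.lumen_radius(theta)
    ro = rl + recipe.wall_thickness(theta)
    la = polygon_area(_polygon_from_radius(theta, rl))
    oa = polygon_area(_polygon_from_radius(theta, ro))
    pa = oa - la
    pb = pa / oa
    r_eff = np.sqrt(la / np.pi)
    lipid_factor = 1.0 + recipe.lipid_depth / recipe.t0 + 0.35 * recipe.arc / np.pi
    stress_proxy = p_dia_kpa * r_eff / recipe.cap_min * lipid_factor
    return np.array([pa, recipe.cap_min, stress_proxy, pb])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the matched {baseline, follow-up} × {IO, IVUS} contour sets.

    Degenerate slice draws (lipid thicker than wall, invalid polygons) are
    regenerated with fresh draws and logged; an impossible configuration is
    rejected up front.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    patient_ids = [f"P{i + 1}" for i in range(config.n_patients)]
    biases = np.clip(
        rng.normal(config.ivus_patient_bias_mean, config.ivus_patient_bias_sd, config.n_patients),
        -0.70,
        0.35,
    )
    (dlo, dhi), (slo, shi) = config.pressure_mmHg
    pressures = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "diastolic_mmHg": rng.uniform(dlo, dhi, config.n_patients),
            "systolic_mmHg": rng.uniform(slo, shi, config.n_patients),
        }
    )

    # pass 1: draw recipes and collect planted-signal predictors
    recipes: list[tuple[str, str, _SliceRecipe]] = []
    preds = []
    for j, pid in enumerate(patient_ids):
        n_slices = int(rng.integers(config.slices_per_patient[0], config.slices_per_patient[1] + 1))
        p_dia_kpa = float(pressures.loc[j, "diastolic_mmHg"]) * MMHG_TO_KPA
        for s in range(n_slices):
            for attempt in range(20):
                recipe = _draw_recipe(rng, config)
                if recipe is not None:
                    break
                logger.warning("degenerate slice draw for %s slice %d, regenerating", pid, s)
            else:
                raise ValueError("could not draw a valid slice geometry; config is impossible")
            recipes.append((pid, f"S{s + 1}", recipe))
            preds.append(_recipe_predictors(recipe, p_dia_kpa))
    preds = np.asarray(preds)

    # pass 2: plant the progression signal on standardized predictors
    sd = preds.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (preds - preds.mean(axis=0)) / sd
    coeffs = np.asarray(config.progression_coefficients, float)
    noise = (
        rng.normal(0.0, config.progression_noise_sd_mm, len(recipes))
        if config.progression_noise_sd_mm > 0
        else np.zeros(len(recipes))
    )
    deltas = config.progression_intercept_mm + z @ coeffs + noise

    slices: list[CohortSlice] = []
    gt_rows = []
    for (pid, sid, recipe), delta in zip(recipes, deltas):
        j = patient_ids.index(pid)
        io_sets = _build_slice_sets(recipe, float(delta))
        sets = {}
        for timepoint, polys in io_sets.items():
            cs: ContourSet = {
                role: SliceContour(pid, sid, timepoint, "IO", role, pts)
                for role, pts in polys.items()
            }
            validate_contour_set(cs)
            sets[(timepoint, "IO")] = cs
            sets[(timepoint, "IVUS")] = degrade_to_ivus(cs, float(biases[j]), config, rng)
        slices.append(CohortSlice(pid, sid, sets))
        gt_rows.append(
            {
                "patient_id": pid,
                "slice_id": sid,
                "planted_delta_mincapt_mm": float(delta),
                "patient_bias": float(biases[j]),
            }
        )

    return Cohort(config, slices, pd.DataFrame(gt_rows), pressures)
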