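"""Zero-pressure starting geometry recovery (circumferential preshrink).

In vivo contours are imaged under pressure and axial stretch.  Solving the
inflation problem on them directly would double-load the vessel, so the
geometry is first shrunk: the lumen is scaled about its centroid by a
circumferential shrink factor, the outwall is rescaled so that wall
cross-section area × axial stretch conserves wall material volume, and
interior boundaries follow by radial interpolation.  The shrink factor is
then calibrated so that inflating the shrunk geometry back to the imaging
pressure (with the axial stretch imposed) reproduces the in vivo lumen
area.

The calibration pressure defaults to diastolic; tolerance on the lumen
area match is 2% relative, with the factor bracketed in [0.85, 1.0].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from capmech.contours import ContourSet
from capmech.femesh import build_mesh
from capmech.geometry import area_centroid, polygon_area
from capmech.materials import MaterialParams
from capmech.solver import ThinLayerModel

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.02
DEFAULT_BRACKET = (0.85, 1.0)
DEFAULT_AXIAL_STRETCH = 1.05


def _star_radius(points: np.ndarray, center: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Boundary radius per angle for a star-shaped polygon (dense resample)."""
    d = points - center
    ang = np.arctan2(d[:, 1], d[:, 0])
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(ang)
    ang_s = ang[order]
    rad_s = rad[order]
    ang_ext = np.concatenate([ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi])
    rad_ext = np.concatenate([rad_s, rad_s, rad_s])
    return np.interp(thetas, ang_ext, rad_ext)


def apply_shrink(
    contours: ContourSet,
    circ_shrink: float,
    axial_stretch: float = DEFAULT_AXIAL_STRETCH,
) -> ContourSet:
    """Shrink in vivo contours to a candidate zero-load geometry.

    The lumen is scaled about its area centroid by ``circ_shrink``; the
    outwall scale follows from wall material-volume conservation,
    s_out = sqrt((s² A_lumen + A_wall / λz) / A_outwall).  Interior
    component boundaries (lipid, calcification) are mapped by linear radial
    interpolation between the lumen and outwall scalings.
    """
    if not (0.0 < circ_shrink <= 1.0):
        raise ValueError("circ_shrink must be in (0, 1]")
    lumen = contours["lumen"]
    outwall = contours["outwall"]
    center = area_centroid(lumen.points)
    a_lum = polygon_area(lumen.points)
    a_out = polygon_area(outwall.points)
    s_l = circ_shrink
    s_o = np.sqrt((s_l**2 * a_lum + (a_out - a_lum) / axial_stretch) / a_out)

    out: ContourSet = {}
    out["lumen"] = lumen.with_points(center + s_l * (lumen.points - center))
    out["outwall"] = outwall.with_points(center + s_o * (outwall.points - center))
    if s_o * np.min(_star_radius(outwall.points, center, np.linspace(0, 2 * np.pi, 90))) <= 0:
        raise ValueError("shrink produced a degenerate outwall")

    for role in ("lipid", "calcification"):
        if role not in contours:
            continue
        pts = contours[role].points
        d = pts - center
        theta = np.arctan2(d[:, 1], d[:, 0])
        r = np.hypot(d[:, 0], d[:, 1])
        r_l = _star_radius(lumen.points, center, theta)
        r_o = _star_radius(outwall.points, center, theta)
        t = np.clip((r - r_l) / (r_o - r_l), 0.0, 1.0)
        r_new = s_l * r_l + t * (s_o * r_o - s_l * r_l)
        if np.any(r_new <= 0):
            raise ValueError("shrink produced contour crossing")
        out[role] = contours[role].with_points(
            center + r_new[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        )
    # reject crossings: shrunk lumen must stay strictly inside shrunk outwall
    thetas = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    rl = _star_radius(out["lumen"].points, center, thetas)
    ro = _star_radius(out["outwall"].points, center, thetas)
    if np.any(ro - rl <= 0):
        raise ValueError("shrink produced lumen/outwall crossing")
    return out


@dataclass
class ShrinkCalibration:
    """Result of the circumferential shrink calibration.

    ``model``/``displacement`` hold the FE solve of the *returned* factor,
    so downstream stress extraction can reuse it instead of re-solving.
    """

    circ_shrink: float
    residual: float  # relative lumen-area mismatch at the returned factor
    trace: list[tuple[float, float]]  # (factor, residual) evaluations
    converged: bool
    model: object | None = None
    displacement: np.ndarray | None = None


def calibrate_shrink(
    contours: ContourSet,
    pressure_kpa: float,
    axial_stretch: float = DEFAULT_AXIAL_STRETCH,
    materials: dict[str, MaterialParams] | None = None,
    mesh_density: float = 0.5,
    tolerance: float = DEFAULT_TOLERANCE,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    max_iter: int = 25,
    initial: float | None = None,
    u0: np.ndarray | None = None,
) -> ShrinkCalibration:
    """Bisection on the shrink factor until re-inflation matches lumen area.

    The pressurized lumen area of the shrunk geometry is matched to the in
    vivo lumen area within ``tolerance`` (relative).  With no bracketing
    sign change in ``bracket`` the failure is reported together with the
    residual curve.
    """
    a_target = polygon_area(contours["lumen"].points)
    trace: list[tuple[float, float]] = []
    if pressure_kpa == 0:
        # no load, no shrink (the axial stretch alone is not treated as load)
        return ShrinkCalibration(1.0, 0.0, [(1.0, 0.0)], True)

    last = {"u": u0}  # model/displacement of the most recent evaluation

    def residual(s: float) -> float:
        shrunk = apply_shrink(contours, s, axial_stretch)
        mesh = build_mesh(shrunk, target_density=mesh_density)
        model = ThinLayerModel(mesh, materials, axial_stretch=axial_stretch)
        # the structured mesh topology is shrink-independent, so the previous
        # evaluation's displacement warm-starts the Newton solve
        u = model.solve(pressure_kpa, u0=last.get("u"))
        last.update(s=s, model=model, u=u)
        ring = (mesh.nodes + u)[mesh.lumen_nodes]
        x, y = ring[:, 0], ring[:, 1]
        area = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        r = (area - a_target) / a_target
        trace.append((s, r))
        return r

    def result(s: float, r: float, converged: bool) -> ShrinkCalibration:
        model = last.get("model") if last.get("s") == s else None
        u = last.get("u") if model is not None else None
        return ShrinkCalibration(s, r, trace, converged, model, u)

    lo, hi = bracket
    r_lo = r_hi = None
    if initial is not None and lo < initial < hi:
        # warm start (e.g. the factor calibrated for a sibling slice)
        r_init = residual(initial)
        if abs(r_init) < tolerance:
            return result(initial, r_init, True)
        # the re-inflated area grows monotonically with the shrink factor
        if r_init > 0:
            hi, r_hi = initial, r_init
        else:
            lo, r_lo = initial, r_init
    if r_hi is None:
        r_hi = residual(hi)
        if abs(r_hi) < tolerance:
            return result(hi, r_hi, True)
    if r_lo is None:
        r_lo = residual(lo)
        if abs(r_lo) < tolerance:
            return result(lo, r_lo, True)
    if r_lo * r_hi > 0:
        raise RuntimeError(
            f"no bracketing shrink factor in [{lo}, {hi}]; residual curve: {trace}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        if abs(r_mid) < tolerance:
            return result(mid, r_mid, True)
        if r_mid * r_lo < 0:
            hi, r_hi = mid, r_mid
        else:
            lo, r_lo = mid, r_mid
    best = min(trace, key=lambda t: abs(t[1]))
    logger.warning("shrink bisection hit max_iter; best residual %.4f", best[1])
    return result(best[0], best[1], abs(best[1]) < tolerance)
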