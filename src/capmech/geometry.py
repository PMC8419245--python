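"""Cross-section cap geometry: Four-Quarter Even-Spacing and morphology.

Each vessel cross-section is divided into 100 parts using 100 evenly spaced
lumen points placed by a Four-Quarter Even-Spacing rule: the lumen contour
is cut into four quarters at its intersections with the principal axes of
the lumen area, and each quarter receives 25 points equally spaced in arc
length.  Each lumen point is connected to the outwall point at the same
quarter-relative arc-length fraction; the length of that connection segment
is the wall thickness, and the distance from the lumen point to the first
crossing of the segment with the lipid boundary is the fibrous-cap
thickness (defined only where the segment meets lipid).

Morphological predictors derived per slice: lumen area (LA), plaque area
(PA = outwall-enclosed area minus LA), plaque burden (PB = PA over
outwall-enclosed area), and minimum / mean cap thickness (MinCapT,
MeanCapT) over the defined cap points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from capmech.contours import ContourSet, SliceContour

N_POINTS = 100
N_QUARTERS = 4
POINTS_PER_QUARTER = N_POINTS // N_QUARTERS


# ---------------------------------------------------------------------------
# low-level polygon helpers


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the vertex array in counterclockwise orientation."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return pts if signed >= 0 else pts[::-1]


def perimeter(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    d = np.roll(pts, -1, axis=0) - pts
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def polygon_area(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def area_centroid(points: np.ndarray) -> np.ndarray:
    pts = ensure_ccw(points)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal directions of the polygon's area about its centroid.

    Returns (major, minor) unit vectors with a deterministic sign
    convention (non-negative x component, tie-broken on y), so repeated
    calls and rigid-motion-consistent inputs give consistent anchors.
    """
    pts = ensure_ccw(points)
    c = area_centroid(pts)
    x, y = pts[:, 0] - c[0], pts[:, 1] - c[1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    # second moments of area about the centroid (green's theorem)
    ixx = np.sum((y**2 + y * yn + yn**2) * cross) / 12.0  # = ∫ y² dA
    iyy = np.sum((x**2 + x * xn + xn**2) * cross) / 12.0  # = ∫ x² dA
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    second = np.array([[iyy, ixy], [ixy, ixx]])  # [[∫x², ∫xy], [∫xy, ∫y²]]
    evals, evecs = np.linalg.eigh(second)
    major, minor = evecs[:, 1], evecs[:, 0]

    def _fix(v: np.ndarray) -> np.ndarray:
        if v[0] < 0 or (v[0] == 0 and v[1] < 0):
            return -v
        return v

    return _fix(major), _fix(minor)


def _closed_ring(points: np.ndarray) -> LineString:
    pts = np.vstack([points, points[:1]])
    return LineString(pts)


def _ray_arc_position(ring: LineString, origin: np.ndarray, direction: np.ndarray) -> float:
    """Arc-length position of the first crossing of an outward ray with the ring."""
    reach = 10.0 * (ring.length + 1.0)
    ray = LineString([origin, origin + direction * reach])
    hit = ring.intersection(ray)
    if hit.is_empty:
        raise ValueError("anchor ray does not intersect the contour")
    if isinstance(hit, Point):
        pt = hit
    else:
        pts = (
            list(hit.geoms)
            if isinstance(hit, MultiPoint)
            else [Point(c) for g in getattr(hit, "geoms", [hit]) for c in g.coords]
        )
        o = Point(origin)
        pt = min(pts, key=lambda p: p.distance(o))
    return float(ring.project(pt))


def _point_at_arc(ring: LineString, s: float) -> np.ndarray:
    p = ring.interpolate(s % ring.length)
    return np.array([p.x, p.y])


# ---------------------------------------------------------------------------
# Four-Quarter Even-Spacing resampling


def quarter_anchors(points: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Centroid and the four anchor ray directions (±major, ±minor axes)."""
    c = area_centroid(points)
    major, minor = principal_axes(points)
    return c, (major, minor, -major, -minor)


def _resample_with_rays(
    points: np.ndarray, origin: np.ndarray, directions: tuple[np.ndarray, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Place 4 × 25 even arc-length points between the ray anchor crossings."""
    pts = ensure_ccw(points)
    if perimeter(pts) <= 0 or polygon_area(pts) <= 0:
        raise ValueError("degenerate contour")
    ring = _closed_ring(pts)
    anchor_s = [_ray_arc_position(ring, origin, d) for d in directions]
    # traverse quarters in ring order starting from the +major-axis anchor
    order = np.argsort(anchor_s)
    start = int(np.where(order == 0)[0][0])
    order = np.roll(order, -start)
    s_sorted = [anchor_s[i] for i in order]

    out = np.empty((N_POINTS, 2))
    quarter = np.empty(N_POINTS, dtype=int)
    total = ring.length
    for q in range(N_QUARTERS):
        s0 = s_sorted[q]
        s1 = s_sorted[(q + 1) % N_QUARTERS]
        span = (s1 - s0) % total
        if span == 0:
            raise ValueError("coincident quarter anchors")
        for k in range(POINTS_PER_QUARTER):
            idx = q * POINTS_PER_QUARTER + k
            out[idx] = _point_at_arc(ring, s0 + span * k / POINTS_PER_QUARTER)
            quarter[idx] = q + 1
    return out, quarter


def resample_lumen(lumen: SliceContour | np.ndarray, anchors=None) -> tuple[np.ndarray, np.ndarray]:
    """Resample a lumen contour into 100 Four-Quarter Even-Spacing points.

    Parameters
    ----------
    lumen:
        Contour or raw (n, 2) vertex array.
    anchors:
        Optional ``(origin, directions)`` pair overriding the default
        principal-axis anchors; used to resample the outwall with the rays
        derived from the lumen.

    Returns
    -------
    points, quarter_index:
        (100, 2) points and the 1–4 quarter assignment per point.
    """
    pts = lumen.points if isinstance(lumen, SliceContour) else np.asarray(lumen, float)
    if perimeter(pts) <= 0 or polygon_area(pts) <= 0:
        raise ValueError("degenerate contour")
    if anchors is None:
        origin, directions = quarter_anchors(pts)
    else:
        origin, directions = anchors
    return _resample_with_rays(pts, origin, directions)


# ---------------------------------------------------------------------------
# cap profile


@dataclass
class CapProfile:
    """Per-point wall/cap thickness along the 100 lumen points of a slice.

    ``cap_thickness`` is NaN where the lumen→outwall connection segment
    meets no lipid; ``valid`` flags points whose connection segment stays
    inside the wall annulus.
    """

    lumen_points: np.ndarray
    outwall_points: np.ndarray
    wall_thickness: np.ndarray
    cap_thickness: np.ndarray
    quarter_index: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.wall_thickness > 0

    @property
    def cap_defined(self) -> np.ndarray:
        return np.isfinite(self.cap_thickness) & self.valid

    @property
    def cap_values(self) -> np.ndarray:
        return self.cap_thickness[self.cap_defined]


def build_cap_profile(contours: ContourSet) -> CapProfile:
    """Wall and cap thickness along paired lumen→outwall connection segments.

    The outwall is resampled 4 × 25 with the anchor rays of the lumen, so
    lumen point *i* pairs with the outwall point at the same
    quarter-relative arc-length fraction.
    """
    lumen = contours["lumen"]
    outwall = contours["outwall"]
    origin, directions = quarter_anchors(lumen.points)
    lum_pts, quarter = _resample_with_rays(lumen.points, origin, directions)
    out_pts, _ = _resample_with_rays(outwall.points, origin, directions)

    seg = out_pts - lum_pts
    wall = np.sqrt((seg**2).sum(axis=1))

    cap = np.full(N_POINTS, np.nan)
    lumen_poly = Polygon(lumen.points)
    outwall_poly = Polygon(outwall.points).buffer(1e-9)
    lipid = contours.get("lipid")
    lipid_boundary = Polygon(lipid.points).exterior if lipid is not None else None

    for i in range(N_POINTS):
        if wall[i] <= 0:
            wall[i] = 0.0
            continue
        segment = LineString([lum_pts[i], out_pts[i]])
        # flag the point invalid when the connection leaves the wall annulus
        if not outwall_poly.covers(segment):
            wall[i] = 0.0
            continue
        inner = segment.intersection(lumen_poly)
        if inner.length > 1e-6 * wall[i] + 1e-9:
            wall[i] = 0.0
            continue
        if lipid_boundary is not None:
            hit = segment.intersection(lipid_boundary)
            if not hit.is_empty:
                origin_pt = Point(lum_pts[i])
                if isinstance(hit, Point):
                    cap[i] = hit.distance(origin_pt)
                else:
                    geoms = getattr(hit, "geoms", [hit])
                    dists = []
                    for g in geoms:
                        if isinstance(g, Point):
                            dists.append(g.distance(origin_pt))
                        else:
                            dists.extend(Point(c).distance(origin_pt) for c in g.coords)
                    cap[i] = min(dists)
    return CapProfile(lum_pts, out_pts, wall, cap, quarter)


# ---------------------------------------------------------------------------
# morphology & error arithmetic


@dataclass
class MorphoFeatures:
    """Morphological predictors of one slice (areas mm², thicknesses mm)."""

    LA: float
    PA: float
    PB: float
    MinCapT: float | None
    MeanCapT: float | None

    @property
    def has_cap(self) -> bool:
        return self.MinCapT is not None


def morpho_features(contours: ContourSet, profile: CapProfile | None = None) -> MorphoFeatures:
    """LA / PA / PB from the contour areas; cap statistics from the profile."""
    if profile is None:
        profile = build_cap_profile(contours)
    la = polygon_area(contours["lumen"].points)
    outwall_area = polygon_area(contours["outwall"].points)
    pa = outwall_area - la
    pb = pa / outwall_area
    caps = profile.cap_values
    if caps.size:
        return MorphoFeatures(la, pa, pb, float(caps.min()), float(caps.mean()))
    return MorphoFeatures(la, pa, pb, None, None)


def pool_cap_values(per_slice_values: list[np.ndarray]) -> np.ndarray:
    """Pool per-point cap values over all lipid slices of a patient."""
    arrays = [np.asarray(v, float) for v in per_slice_values if np.size(v)]
    if not arrays:
        return np.empty(0)
    return np.concatenate(arrays)


def percent_error(io_value: float, ivus_value: float) -> float:
    """IVUS-vs-IO percent error with IO as the gold standard.

    Negative means the IVUS value is below the IO value.
    """
    if io_value == 0:
        raise ValueError("percent error undefined for a zero gold-standard value")
    return (ivus_value - io_value) / io_value * 100.0


def summarize(values) -> tuple[float, float, float, float]:
    """(max, min, mean, sample SD) of a list, as in a Max/Min/Mean±SD row.

    The SD uses the n−1 denominator; for fewer than two values it is NaN.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
    return float(v.max()), float(v.min()), float(v.mean()), sd
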