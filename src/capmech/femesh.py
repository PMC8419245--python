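"""Structured cross-section meshing for the thin-layer plaque models.

The wall annulus between lumen and outwall is meshed with a structured
spoke/layer grid of bilinear quadrilaterals: ``n_theta`` radial spokes cast
from the lumen centroid, each subdivided into radial layers grouped into
three bands — cap (lumen → lipid inner edge), lipid, and outer wall.  Band
boundaries follow the lipid crossing radii on spokes inside the lipid arc
and are interpolated smoothly across the lipid-free part of the
circumference (where all bands are vessel tissue), so element edges conform
to the lumen, outwall, and lipid interfaces.

This realizes the 0.5 mm "3D thin-layer" slice as a one-layer generalized
plane-strain extrusion: in-plane displacement fields with an imposed axial
stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from capmech.contours import ContourSet
from capmech.geometry import area_centroid, polygon_area

TISSUE_CODES = {"vessel": 0, "lipid": 1, "calcification": 2}
TISSUE_NAMES = {v: k for k, v in TISSUE_CODES.items()}

#: slice thickness of the thin-layer models (mm)
SLICE_THICKNESS_MM = 0.5


@dataclass
class FEMesh:
    """Quadrilateral mesh of one cross-section.

    nodes: (nn, 2) reference coordinates in mm; quads: (ne, 4) CCW node
    ids; tissue: (ne,) codes per TISSUE_CODES; lumen_nodes: CCW-ordered
    node ids of the lumen boundary ring.
    """

    nodes: np.ndarray
    quads: np.ndarray
    tissue: np.ndarray
    lumen_nodes: np.ndarray
    center: np.ndarray
    n_theta: int
    n_layers: int
    thickness: float = SLICE_THICKNESS_MM
    density: float = 1.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.quads)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.quads].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        x = self.nodes[self.quads]
        # shoelace per quad
        xs, ys = x[..., 0], x[..., 1]
        return 0.5 * np.abs(
            np.sum(xs * np.roll(ys, -1, axis=1) - np.roll(xs, -1, axis=1) * ys, axis=1)
        )

    def tissue_areas(self) -> dict[str, float]:
        areas = self.element_areas()
        return {
            name: float(areas[self.tissue == code].sum())
            for name, code in TISSUE_CODES.items()
            if np.any(self.tissue == code)
        }

    def fiber_directions(self) -> np.ndarray:
        """Reference circumferential unit vector per element (about the centroid)."""
        d = self.element_centroids() - self.center
        r = np.hypot(d[:, 0], d[:, 1])
        t = np.column_stack([-d[:, 1], d[:, 0]]) / r[:, None]
        return t


def _ray_crossings(ring: LineString, center: np.ndarray, theta: float, reach: float) -> list[float]:
    ray = LineString([center, center + reach * np.array([np.cos(theta), np.sin(theta)])])
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


def _interp_gap(values: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Circular linear interpolation of band fractions across undefined spokes."""
    n = len(values)
    if defined.all():
        return values
    if not defined.any():
        return values  # caller fills a constant
    out = values.copy()
    idx = np.where(defined)[0]
    for i in np.where(~defined)[0]:
        # nearest defined neighbours in circular index distance
        prev = idx[np.argmin((i - idx) % n)]
        nxt = idx[np.argmin((idx - i) % n)]
        dp, dn = (i - prev) % n, (nxt - i) % n
        w = dn / (dp + dn)
        out[i] = w * values[prev] + (1 - w) * values[nxt]
    return out


def build_mesh(
    contours: ContourSet,
    target_density: float = 1.0,
    base_theta: int = 64,
    base_layers: tuple[int, int, int] = (2, 3, 4),
) -> FEMesh:
    """Conforming structured quad mesh of the wall annulus.

    ``target_density`` scales the spoke and layer counts by √density, so a
    10% density increase grows the element count by ~10%.
    """
    lumen = contours["lumen"].points
    outwall = contours["outwall"].points
    scale = float(np.sqrt(target_density))
    n_theta = max(24, int(round(base_theta * scale)))
    n_cap = max(2, int(round(base_layers[0] * scale)))
    n_lip = max(2, int(round(base_layers[1] * scale)))
    n_out = max(2, int(round(base_layers[2] * scale)))
    n_layers = n_cap + n_lip + n_out

    center = area_centroid(lumen)
    reach = 10.0 * (np.abs(outwall - center).max() + 1.0)
    lumen_ring = LineString(np.vstack([lumen, lumen[:1]]))
    out_ring = LineString(np.vstack([outwall, outwall[:1]]))
    lipid = contours.get("lipid")
    lipid_ring = (
        LineString(np.vstack([lipid.points, lipid.points[:1]])) if lipid is not None else None
    )

    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r_l = np.empty(n_theta)
    r_o = np.empty(n_theta)
    t_in = np.full(n_theta, np.nan)
    t_out = np.full(n_theta, np.nan)
    for k, th in enumerate(thetas):
        lh = _ray_crossings(lumen_ring, center, th, reach)
        oh = _ray_crossings(out_ring, center, th, reach)
        if not lh or not oh:
            raise ValueError("spoke misses a boundary: contour not star-shaped about centroid")
        r_l[k], r_o[k] = lh[-1], oh[-1]
        if r_o[k] <= r_l[k]:
            raise ValueError("outwall inside lumen along a spoke: boundary intersection")
        if lipid_ring is not None:
            ph = _ray_crossings(lipid_ring, center, th, reach)
            if len(ph) >= 2 and ph[-1] - ph[0] > 1e-6:
                t_in[k] = (ph[0] - r_l[k]) / (r_o[k] - r_l[k])
                t_out[k] = (ph[-1] - r_l[k]) / (r_o[k] - r_l[k])

    in_lipid = np.isfinite(t_in)
    if in_lipid.any():
        t_in = _interp_gap(np.where(in_lipid, t_in, 0.0), in_lipid)
        t_out = _interp_gap(np.where(in_lipid, t_out, 0.0), in_lipid)
    else:
        t_in[:] = 1.0 / 3.0
        t_out[:] = 2.0 / 3.0
    t_in = np.clip(t_in, 0.02, 0.93)
    t_out = np.clip(t_out, t_in + 0.02, 0.96)

    # radial node fractions per spoke: bands [0, t_in], [t_in, t_out], [t_out, 1]
    frac = np.empty((n_theta, n_layers + 1))
    for k in range(n_theta):
        frac[k] = np.concatenate(
            [
                np.linspace(0.0, t_in[k], n_cap + 1)[:-1],
                np.linspace(t_in[k], t_out[k], n_lip + 1)[:-1],
                np.linspace(t_out[k], 1.0, n_out + 1),
            ]
        )
    radii = r_l[:, None] + frac * (r_o - r_l)[:, None]
    nodes = np.empty((n_theta * (n_layers + 1), 2))
    for k, th in enumerate(thetas):
        u = np.array([np.cos(th), np.sin(th)])
        nodes[k * (n_layers + 1) : (k + 1) * (n_layers + 1)] = center + radii[k][:, None] * u

    def nid(k: int, j: int) -> int:
        return (k % n_theta) * (n_layers + 1) + j

    quads = []
    tissue = []
    lipid_band = range(n_cap, n_cap + n_lip)
    for k in range(n_theta):
        k2 = (k + 1) % n_theta
        for j in range(n_layers):
            quads.append([nid(k, j), nid(k, j + 1), nid(k2, j + 1), nid(k2, j)])
            if j in lipid_band and in_lipid.any() and in_lipid[k] and in_lipid[k2]:
                tissue.append(TISSUE_CODES["lipid"])
            else:
                tissue.append(TISSUE_CODES["vessel"])
    quads = np.asarray(quads, dtype=int)
    tissue = np.asarray(tissue, dtype=int)

    calc = contours.get("calcification")
    if calc is not None:
        calc_poly = Polygon(calc.points)
        cents = nodes[quads].mean(axis=1)
        inside = np.array([calc_poly.contains(Point(p)) for p in cents])
        tissue[inside] = TISSUE_CODES["calcification"]

    mesh = FEMesh(
        nodes=nodes,
        quads=quads,
        tissue=tissue,
        lumen_nodes=np.array([nid(k, 0) for k in range(n_theta)]),
        center=center,
        n_theta=n_theta,
        n_layers=n_layers,
        density=target_density,
    )
    # diagnostic: the mesh must cover the annulus area
    annulus = polygon_area(outwall) - polygon_area(lumen)
    covered = float(mesh.element_areas().sum())
    if abs(covered - annulus) > 0.02 * annulus:
        raise ValueError(
            f"mesh area {covered:.4f} deviates from annulus area {annulus:.4f}: bad boundaries"
        )
    return mesh
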