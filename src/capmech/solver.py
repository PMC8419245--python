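"""Quasi-static inflation of thin-layer plaque cross-sections.

Solves the generalized plane-strain boundary-value problem on the meshed
wall annulus: modified Mooney–Rivlin tissue (vessel anisotropic, plaque
components isotropic), imposed axial stretch λz, follower pressure on the
lumen boundary, traction-free outwall, rigid-body modes removed by three
global Lagrange constraints.  The discretization uses bilinear quads with
2×2 Gauss quadrature for the isochoric energy and a single reduced
(centroid) point for the volumetric penalty — the standard selective
reduced integration that avoids volumetric locking near incompressibility.

Newton's method with incremental load stepping drives the residual below
1e-8 relative; diverging steps are retried at half the load increment.
The follower pressure is conservative on a closed cavity, with potential
−p·λz·A_cavity(deformed lumen), so its residual and tangent come from the
shoelace area gradient of the lumen ring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from capmech.femesh import FEMesh, TISSUE_CODES, TISSUE_NAMES
from capmech.geometry import CapProfile
from capmech.materials import (
    DEFAULT_MATERIALS,
    MaterialParams,
    cauchy_2d,
    energy_and_piola_2d,
    validate_material,
)

logger = logging.getLogger(__name__)

MMHG_TO_KPA = 0.133322

_CORNERS = np.array([(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)])
_GAUSS_2x2 = np.array([(s, t) for s in (-1 / np.sqrt(3), 1 / np.sqrt(3)) for t in (-1 / np.sqrt(3), 1 / np.sqrt(3))])


def _shape_grad(xi: float, eta: float) -> np.ndarray:
    """dN/d(xi,eta) for the bilinear quad, (4, 2)."""
    g = np.empty((4, 2))
    for a, (xa, ea) in enumerate(_CORNERS):
        g[a, 0] = 0.25 * xa * (1 + ea * eta)
        g[a, 1] = 0.25 * ea * (1 + xa * xi)
    return g


class SolverError(RuntimeError):
    pass


class _Diverged(Exception):
    pass


@dataclass
class StressStrainResult:
    """Converged nodal fields and the evaluation conditions.

    ``nodal_stress``: maximum-principal Cauchy stress (kPa);
    ``nodal_strain``: maximum-principal Green–Lagrange strain.
    """

    mesh: FEMesh
    displacement: np.ndarray
    nodal_stress: np.ndarray
    nodal_strain: np.ndarray
    pressure_kpa: float
    axial_stretch: float

    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacement

    def deformed_lumen_area(self) -> float:
        ring = self.deformed_nodes()[self.mesh.lumen_nodes]
        x, y = ring[:, 0], ring[:, 1]
        return float(abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


class ThinLayerModel:
    """Assembled FE model for one meshed cross-section."""

    def __init__(
        self,
        mesh: FEMesh,
        materials: dict[str, MaterialParams] | None = None,
        axial_stretch: float = 1.05,
    ):
        self.mesh = mesh
        self.materials = dict(DEFAULT_MATERIALS if materials is None else materials)
        self.lz = float(axial_stretch)
        for name in set(TISSUE_NAMES[c] for c in np.unique(mesh.tissue)):
            validate_material(self.materials[name])

        self.X = mesh.nodes[mesh.quads]  # (ne, 4, 2)
        ne = mesh.n_elements
        # per-element material parameter arrays
        self.params = {}
        keys = ("c1", "c2", "D1", "D2", "K1", "K2", "kappa")
        arr = {k: np.empty(ne) for k in keys}
        for name, code in TISSUE_CODES.items():
            sel = mesh.tissue == code
            if not sel.any():
                continue
            m = self.materials[name]
            vals = dict(c1=m.c1, c2=m.c2, D1=m.D1, D2=m.D2, kappa=m.kappa)
            vals["K1"] = m.K1 if m.anisotropic else 0.0
            vals["K2"] = m.K2 if m.anisotropic else 1.0
            for k in keys:
                arr[k][sel] = vals[k]
        self.params = arr
        self.nc = mesh.fiber_directions()  # (ne, 2)

        # quadrature geometry
        self.gp_G = []  # per gp: (ne, 4, 2) shape gradients
        self.gp_w = []  # per gp: (ne,) weights
        for xi, eta in _GAUSS_2x2:
            g = _shape_grad(xi, eta)
            Jm = np.einsum("eai,aj->eij", self.X, g)
            det = Jm[:, 0, 0] * Jm[:, 1, 1] - Jm[:, 0, 1] * Jm[:, 1, 0]
            if np.any(det <= 0):
                raise SolverError("non-positive element Jacobian (inverted quad)")
            Jinv = np.linalg.inv(Jm)
            self.gp_G.append(np.einsum("aj,eji->eai", g, Jinv))
            self.gp_w.append(det)
        g0 = _shape_grad(0.0, 0.0)
        Jm = np.einsum("eai,aj->eij", self.X, g0)
        det = Jm[:, 0, 0] * Jm[:, 1, 1] - Jm[:, 0, 1] * Jm[:, 1, 0]
        self.c_G = np.einsum("aj,eji->eai", g0, np.linalg.inv(Jm))
        self.c_w = det * 4.0

        self._params_vol = {
            **{k: self.params[k] for k in ("kappa",)},
            "c1": np.zeros(ne),
            "c2": np.zeros(ne),
            "D1": np.zeros(ne),
            "D2": np.zeros(ne),
            "K1": np.zeros(ne),
            "K2": np.ones(ne),
        }

    # -- internal forces ---------------------------------------------------

    def _element_forces(self, u_e: np.ndarray, lz: float) -> np.ndarray:
        """Element internal force vectors (ne, 4, 2)."""
        uT = np.swapaxes(u_e, 1, 2)
        f = np.zeros_like(u_e)
        for G, w in zip(self.gp_G, self.gp_w):
            Fp = np.eye(2) + uT @ G
            _, Pp = energy_and_piola_2d(Fp, lz, self.params, self.nc, volumetric=False)
            f += w[:, None, None] * (G @ np.swapaxes(Pp, 1, 2))
        Fp = np.eye(2) + uT @ self.c_G
        _, Pv = energy_and_piola_2d(Fp, lz, self._params_vol, self.nc, volumetric=True)
        f += self.c_w[:, None, None] * (self.c_G @ np.swapaxes(Pv, 1, 2))
        return f

    def internal_force(self, u: np.ndarray, lz: float) -> np.ndarray:
        f_e = self._element_forces(u[self.mesh.quads], lz)
        f = np.zeros_like(u)
        np.add.at(f, self.mesh.quads, f_e)
        return f

    def stiffness(
        self, u: np.ndarray, lz: float, f0_e: np.ndarray | None = None, h: float = 1e-7
    ) -> sp.csr_matrix:
        """Tangent of the internal forces by forward differences per element dof.

        ``f0_e`` may pass in the element forces already computed for the
        residual at ``u``.  A finite-difference tangent only affects the
        Newton path, not the converged residual.
        """
        quads = self.mesh.quads
        ne = self.mesh.n_elements
        u_e = u[quads]
        if f0_e is None:
            f0_e = self._element_forces(u_e, lz)
        K_e = np.empty((ne, 8, 8))
        for d in range(8):
            a, i = divmod(d, 2)
            up = u_e.copy()
            up[:, a, i] += h
            col = (self._element_forces(up, lz) - f0_e) / h
            K_e[:, :, d] = col.reshape(ne, 8)
        dof = (2 * quads[:, :, None] + np.arange(2)[None, None, :]).reshape(ne, 8)
        rows = np.repeat(dof, 8, axis=1).ravel()
        cols = np.tile(dof, (1, 8)).ravel()
        n = 2 * self.mesh.n_nodes
        return sp.coo_matrix((K_e.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    # -- follower pressure -------------------------------------------------

    def external_force(self, u: np.ndarray, pressure: float, lz: float) -> np.ndarray:
        """Nodal forces of the cavity pressure, −∂(−p·lz·A_cav)/∂u."""
        ln = self.mesh.lumen_nodes
        ring = (self.mesh.nodes + u)[ln]
        nxt = np.roll(ring, -1, axis=0)
        prv = np.roll(ring, 1, axis=0)
        dA = 0.5 * np.column_stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]])
        f = np.zeros_like(u)
        f[ln] = pressure * lz * dA
        return f

    def external_stiffness(self, pressure: float, lz: float) -> sp.csr_matrix:
        """∂f_ext/∂u (constant, from the shoelace-area Hessian)."""
        ln = self.mesh.lumen_nodes
        m = len(ln)
        rows, cols, vals = [], [], []
        c = 0.5 * pressure * lz
        for k in range(m):
            kn = (k + 1) % m
            kp = (k - 1) % m
            # d f_x(k) / d y(k+1) = c ; d f_x(k) / d y(k-1) = -c
            rows += [2 * ln[k], 2 * ln[k], 2 * ln[k] + 1, 2 * ln[k] + 1]
            cols += [2 * ln[kn] + 1, 2 * ln[kp] + 1, 2 * ln[kp], 2 * ln[kn]]
            vals += [c, -c, c, -c]
        n = 2 * self.mesh.n_nodes
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    # -- constraints -------------------------------------------------------

    def _constraint_matrix(self) -> sp.csr_matrix:
        nn = self.mesh.n_nodes
        X = self.mesh.nodes - self.mesh.center
        rows, cols, vals = [], [], []
        for i in range(nn):
            rows += [0, 1]
            cols += [2 * i, 2 * i + 1]
            vals += [1.0 / nn, 1.0 / nn]
            rows += [2, 2]
            cols += [2 * i, 2 * i + 1]
            vals += [-X[i, 1] / nn, X[i, 0] / nn]
        return sp.coo_matrix((vals, (rows, cols)), shape=(3, 2 * nn)).tocsr()

    # -- solve -------------------------------------------------------------

    def _newton(
        self,
        u: np.ndarray,
        pressure: float,
        lz: float,
        tol: float = 1e-8,
        max_iter: int = 15,
    ) -> tuple[np.ndarray, int]:
        n = 2 * self.mesh.n_nodes
        C = self._constraint_matrix()
        f_ext0 = self.external_force(u, pressure, lz)
        ref = max(float(np.linalg.norm(f_ext0)), 1.0)
        lam = np.zeros(3)
        best_res = np.inf
        for it in range(max_iter):
            try:
                f_e = self._element_forces(u[self.mesh.quads], lz)
                f_int = np.zeros_like(u)
                np.add.at(f_int, self.mesh.quads, f_e)
                r = f_int - self.external_force(u, pressure, lz)
                res = float(np.linalg.norm(r))
            except FloatingPointError as exc:
                raise _Diverged(str(exc))
            if res < tol * ref and it > 0:
                return u, it
            if not np.isfinite(res) or res > 1e8 * ref:
                raise _Diverged(f"residual blow-up at iteration {it}")
            if it >= 3 and res > 50.0 * best_res:
                raise _Diverged(f"residual diverging at iteration {it}")
            best_res = min(best_res, res)
            try:
                K = self.stiffness(u, lz, f0_e=f_e) - self.external_stiffness(pressure, lz)
            except FloatingPointError as exc:
                raise _Diverged(str(exc))
            A = sp.bmat([[K, C.T], [C, None]], format="csc")
            rhs = np.concatenate([-(r.ravel() + C.T @ lam), -(C @ u.ravel())])
            try:
                sol = spla.spsolve(A, rhs)
            except Exception as exc:  # singular system
                raise _Diverged(str(exc))
            du = sol[:n].reshape(-1, 2)
            lam = lam + sol[n:]
            if not np.all(np.isfinite(du)):
                raise _Diverged("non-finite Newton update")
            u = u + du
        raise _Diverged(f"no convergence in {max_iter} Newton iterations (res={res:.3e})")

    def solve(
        self, pressure_kpa: float, n_steps: int = 2, u0: np.ndarray | None = None
    ) -> np.ndarray:
        """Displacement field at the given lumen pressure (kPa).

        Ramps pressure and axial stretch together in ``n_steps`` load
        increments, halving the increment on Newton divergence down to a
        minimum step of 1/64 of the load.  A warm-start displacement ``u0``
        (e.g. the solution on a slightly different shrink of the same
        structured mesh) is tried at full load first.
        """
        if pressure_kpa < 0:
            raise ValueError("pressure must be non-negative")
        old_err = np.seterr(over="raise", invalid="raise")
        try:
            if u0 is not None and u0.shape == self.mesh.nodes.shape:
                try:
                    u_full, _ = self._newton(u0.copy(), pressure_kpa, self.lz)
                    return u_full
                except _Diverged:
                    logger.debug("warm start rejected; falling back to load stepping")
            u = np.zeros_like(self.mesh.nodes)
            u_prev = None
            s = 0.0
            s_prev = 0.0
            ds = 1.0 / n_steps
            while s < 1.0 - 1e-12:
                target = min(1.0, s + ds)
                lz = 1.0 + (self.lz - 1.0) * target
                guess = u.copy()
                if u_prev is not None and s > s_prev:
                    # secant predictor along the load path
                    guess += (u - u_prev) * ((target - s) / (s - s_prev))
                try:
                    u_new, iters = self._newton(guess, pressure_kpa * target, lz)
                except _Diverged as exc:
                    ds /= 2.0
                    if ds < 1.0 / 64.0:
                        raise SolverError(
                            f"load stepping failed below minimum increment: {exc}"
                        ) from exc
                    logger.debug("halving load step to %.4f (%s)", ds, exc)
                    continue
                u_prev, s_prev = u, s
                u, s = u_new, target
                if iters <= 4:
                    ds *= 1.5
            return u
        finally:
            np.seterr(**old_err)


# ---------------------------------------------------------------------------
# field extraction


def stress_strain_fields(
    model: ThinLayerModel, displacement: np.ndarray, pressure_kpa: float
) -> StressStrainResult:
    """Nodal maximum-principal Cauchy stress and Green strain.

    Gauss-point tensors are reduced to element means and scattered to the
    nodes by area-weighted averaging of adjacent elements.
    """
    mesh = model.mesh
    u_e = displacement[mesh.quads]
    params_dev = {**model.params, "kappa": np.zeros(mesh.n_elements)}

    sig_gp = np.empty((len(model.gp_G), mesh.n_elements))
    eps_gp = np.empty_like(sig_gp)
    for g, (G, _w) in enumerate(zip(model.gp_G, model.gp_w)):
        Fp = np.eye(2) + np.einsum("eai,eaj->eij", u_e, G)
        sigma, E = cauchy_2d(Fp, model.lz, params_dev, model.nc)
        sig_gp[g] = np.linalg.eigvalsh(sigma)[:, -1]
        eps_gp[g] = np.linalg.eigvalsh(E)[:, -1]

    # adding the (isotropic) penalty pressure shifts every eigenvalue, so
    # the principal value of the full stress is principal(dev) + p_vol
    s_node = _gp_to_nodes(model, sig_gp) + _nodal_penalty_pressure(model, u_e)
    e_node = _gp_to_nodes(model, eps_gp)
    return StressStrainResult(
        mesh=mesh,
        displacement=displacement,
        nodal_stress=s_node,
        nodal_strain=e_node,
        pressure_kpa=pressure_kpa,
        axial_stretch=model.lz,
    )


def _nodal_penalty_pressure(model: ThinLayerModel, u_e: np.ndarray) -> np.ndarray:
    """Nodal volumetric (penalty) pressure κ(J−1).

    Under selective reduced integration only the centroid J is controlled
    by equilibrium, so the pressure is taken element-wise at the centroid
    and rebuilt as a nodal field on the structured spoke/layer grid:
    tangential averaging between adjacent spokes, radial averaging between
    adjacent layers, and linear radial extrapolation at the lumen/outwall
    rings (gauss-point J is polluted by parasitic bilinear modes and is
    not usable directly).
    """
    mesh = model.mesh
    Fp_c = np.eye(2) + np.einsum("eai,eaj->eij", u_e, model.c_G)
    J_c = (Fp_c[:, 0, 0] * Fp_c[:, 1, 1] - Fp_c[:, 0, 1] * Fp_c[:, 1, 0]) * model.lz
    p_el = model.params["kappa"] * (J_c - 1.0)
    nt, L = mesh.n_theta, mesh.n_layers
    P = p_el.reshape(nt, L)
    Pc = 0.5 * (np.roll(P, 1, axis=0) + P)
    N = np.empty((nt, L + 1))
    N[:, 1:L] = 0.5 * (Pc[:, : L - 1] + Pc[:, 1:])
    N[:, 0] = 1.5 * Pc[:, 0] - 0.5 * Pc[:, 1]
    N[:, L] = 1.5 * Pc[:, L - 1] - 0.5 * Pc[:, L - 2]
    return N.ravel()


def _gp_to_nodes(model: ThinLayerModel, gp_vals: np.ndarray) -> np.ndarray:
    """Bilinear gauss→corner extrapolation plus area-weighted nodal average."""
    mesh = model.mesh
    r3 = np.sqrt(3.0)
    M = np.empty((4, len(_GAUSS_2x2)))
    for a, (xa, ea) in enumerate(_CORNERS):
        for g, (xg, eg) in enumerate(_GAUSS_2x2):
            M[a, g] = 0.25 * (1.0 + r3 * np.sign(xg) * xa) * (1.0 + r3 * np.sign(eg) * ea)
    corner = M @ gp_vals
    areas = mesh.element_areas()
    w_node = np.zeros(mesh.n_nodes)
    v_node = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(w_node, mesh.quads[:, a], areas)
        np.add.at(v_node, mesh.quads[:, a], areas * corner[a])
    return v_node / w_node


@dataclass
class CapAggregates:
    MaxCapS: float
    MeanCapS: float
    MaxCapSn: float
    MeanCapSn: float

    def as_dict(self) -> dict[str, float]:
        return {
            "MaxCapS": self.MaxCapS,
            "MeanCapS": self.MeanCapS,
            "MaxCapSn": self.MaxCapSn,
            "MeanCapSn": self.MeanCapSn,
        }

def cap_aggregates(result: StressStrainResult, profile: CapProfile) -> CapAggregates | None:
    """Cap stress/strain aggregates over the cap lumen points.

    Each cap lumen point (a point of the in vivo cap profile where cap
    thickness is defined) is matched to the nearest deformed lumen-boundary
    node; aggregates are taken over those nodal values.  Returns None when
    the slice has no cap points.
    """
    sel = profile.cap_defined
    if not sel.any():
        return None
    pts = profile.lumen_points[sel]
    lumen_nodes = result.mesh.lumen_nodes
    ring = result.deformed_nodes()[lumen_nodes]
    d2 = ((pts[:, None, :] - ring[None, :, :]) ** 2).sum(axis=2)
    nearest = lumen_nodes[np.argmin(d2, axis=1)]
    s = result.nodal_stress[nearest]
    e = result.nodal_strain[nearest]
    agg = CapAggregates(float(s.max()), float(s.mean()), float(e.max()), float(e.mean()))
    agg._points = (s, e)  # type: ignore[attr-defined]
    return agg


def nodal_hoop_stress(model: ThinLayerModel, displacement: np.ndarray) -> np.ndarray:
    """Nodal circumferential (hoop) Cauchy stress, for benchmark comparison.

    Projects the gauss-point stress tensors on the deformed tangential
    direction about the section center, then extrapolates to nodes like
    :func:`stress_strain_fields`.
    """
    mesh = model.mesh
    u_e = displacement[mesh.quads]
    params_dev = {**model.params, "kappa": np.zeros(mesh.n_elements)}
    x_e = (mesh.nodes + displacement)[mesh.quads]
    cen = x_e.mean(axis=1)
    d = cen - model.mesh.center
    r = np.hypot(d[:, 0], d[:, 1])
    t = np.column_stack([-d[:, 1], d[:, 0]]) / r[:, None]

    hoop_gp = np.empty((len(model.gp_G), mesh.n_elements))
    for g, G in enumerate(model.gp_G):
        Fp = np.eye(2) + np.einsum("eai,eaj->eij", u_e, G)
        sigma, _E = cauchy_2d(Fp, model.lz, params_dev, model.nc)
        hoop_gp[g] = np.einsum("ei,eij,ej->e", t, sigma[:, :2, :2], t)
    return _gp_to_nodes(model, hoop_gp) + _nodal_penalty_pressure(model, u_e)


# ---------------------------------------------------------------------------
# mesh convergence


def mesh_convergence(
    build_model,
    pressure_kpa: float,
    profile: CapProfile,
    quantity: str = "MaxCapS",
    rel_tol: float = 0.02,
    density0: float = 1.0,
    max_refinements: int = 10,
) -> tuple[StressStrainResult, CapAggregates, list[tuple[float, float]]]:
    """Refine mesh density by 10% until the tracked quantity changes < 2%.

    ``build_model(density)`` must return a ready :class:`ThinLayerModel`.
    Returns the last solution, its cap aggregates, and the
    (density, quantity) convergence trace.
    """
    trace: list[tuple[float, float]] = []
    density = density0
    prev = None
    last = None
    for _ in range(max_refinements + 1):
        model = build_model(density)
        u = model.solve(pressure_kpa)
        result = stress_strain_fields(model, u, pressure_kpa)
        agg = cap_aggregates(result, profile)
        if agg is None:
            raise SolverError("no cap points: convergence quantity undefined")
        q = agg.as_dict()[quantity]
        trace.append((density, q))
        if prev is not None and abs(q - prev) <= rel_tol * abs(q):
            return result, agg, trace
        prev = q
        last = (result, agg)
        density *= 1.1
    raise SolverError(f"mesh convergence not reached in {max_refinements} refinements: {trace}")
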