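"""Modified Mooney–Rivlin constitutive model for vessel wall and plaque tissue.

The strain-energy density per unit reference volume is

    W_iso   = c1 (I1 − 3) + c2 (I2 − 3) + D1 [exp(D2 (I1 − 3)) − 1]
    W_aniso = W_iso + K1/K2 {exp[K2 (I4 − 1)²] − 1}

with I1, I2 the first and second invariants of the right Cauchy–Green
tensor C = FᵀF, and I4 = C : (n_c ⊗ n_c) the squared stretch along the
circumferential fiber direction n_c.  Vessel/fibrous tissue is anisotropic
(fiber-reinforced along n_c); lipid and calcification are isotropic.
Near-incompressibility is enforced by a volumetric penalty κ/2 (J − 1)².

The vessel parameter set quotes a calibration in which c1 is negative
(−262.76 kPa); the energy is only meaningful in the full expression where
the exponential D1/D2 term dominates.  ``validate_material`` checks that W
grows monotonically away from the identity along equibiaxial radial
stretch in [0.9, 1.3] and fails loudly otherwise.

Near-incompressibility uses the standard volumetric–isochoric split: the
Mooney–Rivlin terms are evaluated on the reduced invariants
Ī1 = J^(−2/3) I1, Ī2 = J^(−4/3) I2, Ī4 = J^(−2/3) I4, plus the penalty
κ/2 (J − 1)².  On the incompressible manifold (J = 1) the split energy
coincides exactly with the printed expressions; away from it the split
makes the deviatoric stress traceless, so the stress vanishes at the
identity instead of leaving a spurious hydrostatic offset for the penalty
to relax.

Units: stresses and energy densities in kPa, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# default bulk-like penalty modulus (kPa) for near-incompressibility
DEFAULT_KAPPA = 3.0e3


@dataclass(frozen=True)
class MaterialParams:
    """Constants of the modified Mooney–Rivlin model for one tissue class."""

    c1: float  # kPa
    c2: float  # kPa
    D1: float  # kPa
    D2: float  # dimensionless
    K1: float = 0.0  # kPa (fiber stiffness; 0 disables the anisotropic term)
    K2: float = 1.0  # dimensionless
    kappa: float = DEFAULT_KAPPA  # kPa, volumetric penalty
    anisotropic: bool = False
    name: str = "material"


#: Literature parameter sets for the three tissue classes (kPa).
VESSEL = MaterialParams(
    c1=-262.76, c2=22.9, D1=125.9, D2=2.0, K1=7.19, K2=23.5, anisotropic=True, name="vessel"
)
LIPID = MaterialParams(c1=0.5, c2=0.0, D1=0.5, D2=1.5, name="lipid")
CALCIFICATION = MaterialParams(c1=92.0, c2=0.0, D1=36.0, D2=2.0, name="calcification")

DEFAULT_MATERIALS = {"vessel": VESSEL, "lipid": LIPID, "calcification": CALCIFICATION}


@dataclass
class DeformationState:
    """Deformation gradient with derived invariants (3×3, J > 0)."""

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float).reshape(3, 3)

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I2(self) -> float:
        C = self.C
        return float(0.5 * (np.trace(C) ** 2 - np.trace(C @ C)))

    def I4(self, nc: np.ndarray) -> float:
        nc = np.asarray(nc, dtype=float)
        nc = nc / np.linalg.norm(nc)
        return float(nc @ self.C @ nc)


def strain_energy(
    state: DeformationState,
    mat: MaterialParams,
    nc: np.ndarray | None = None,
    include_volumetric: bool = True,
) -> float:
    """Strain-energy density (kPa) of a deformation state.

    For anisotropic materials ``nc`` is the reference-configuration fiber
    (circumferential) direction; it defaults to the first basis vector.
    """
    J = state.J
    if J <= 0:
        raise ValueError("non-positive Jacobian: inadmissible deformation state")
    i1 = state.I1 * J ** (-2.0 / 3.0)
    i2 = state.I2 * J ** (-4.0 / 3.0)
    w = mat.c1 * (i1 - 3.0) + mat.c2 * (i2 - 3.0) + mat.D1 * (np.exp(mat.D2 * (i1 - 3.0)) - 1.0)
    if mat.anisotropic and mat.K1 != 0.0:
        if nc is None:
            nc = np.array([1.0, 0.0, 0.0])
        n = np.asarray(nc, dtype=float)
        if n.size == 2:
            n = np.array([n[0], n[1], 0.0])
        i4 = state.I4(n) * J ** (-2.0 / 3.0)
        w += mat.K1 / mat.K2 * (np.exp(mat.K2 * (i4 - 1.0) ** 2) - 1.0)
    if include_volumetric:
        w += 0.5 * mat.kappa * (J - 1.0) ** 2
    return float(w)


def second_piola(
    state: DeformationState, mat: MaterialParams, nc: np.ndarray | None = None
) -> np.ndarray:
    """Second Piola–Kirchhoff stress S = 2 ∂W/∂C (kPa), analytic."""
    C = state.C
    Cinv = np.linalg.inv(C)
    J = state.J
    jm23 = J ** (-2.0 / 3.0)
    i1b = state.I1 * jm23
    i2b = state.I2 * jm23**2
    w1 = mat.c1 + mat.D1 * mat.D2 * np.exp(mat.D2 * (i1b - 3.0))
    w2 = mat.c2
    eye = np.eye(3)
    S = 2.0 * (
        w1 * jm23 * (eye - state.I1 / 3.0 * Cinv)
        + w2 * jm23**2 * (state.I1 * eye - C - 2.0 * state.I2 / 3.0 * Cinv)
    )
    if mat.anisotropic and mat.K1 != 0.0:
        if nc is None:
            nc = np.array([1.0, 0.0, 0.0])
        n = np.asarray(nc, dtype=float)
        if n.size == 2:
            n = np.array([n[0], n[1], 0.0])
        n = n / np.linalg.norm(n)
        i4 = float(n @ C @ n)
        i4b = i4 * jm23
        w4 = 2.0 * mat.K1 * (i4b - 1.0) * np.exp(mat.K2 * (i4b - 1.0) ** 2)
        S += 2.0 * w4 * jm23 * (np.outer(n, n) - i4 / 3.0 * Cinv)
    S += mat.kappa * (J - 1.0) * J * Cinv
    return S


def cauchy_stress(
    state: DeformationState, mat: MaterialParams, nc: np.ndarray | None = None
) -> np.ndarray:
    """Cauchy stress σ = J⁻¹ F S Fᵀ (kPa)."""
    S = second_piola(state, mat, nc)
    F = state.F
    return (F @ S @ F.T) / state.J


def validate_material(mat: MaterialParams, stretch_range=(0.9, 1.3), n: int = 81) -> None:
    """Fail loudly if W is not monotone away from identity on radial stretch.

    Checks the energy along the equibiaxial in-plane stretch path
    F = diag(λ, λ, 1/λ²) (isochoric) for λ in ``stretch_range``: W must be
    non-negative and non-decreasing in |λ − 1|.  Guards against parameter
    sets (notably a negative c1) that are only convex inside the full
    expression's working range.
    """
    lams = np.linspace(stretch_range[0], stretch_range[1], n)
    ws = []
    for lam in lams:
        F = np.diag([lam, lam, 1.0 / lam**2])
        ws.append(strain_energy(DeformationState(F), mat, include_volumetric=False))
    ws = np.asarray(ws)
    if np.any(ws < -1e-9):
        raise ValueError(f"{mat.name}: strain energy negative along radial stretch path")
    tol = 1e-6 * max(1.0, np.abs(ws).max())
    upper = ws[lams >= 1.0]  # must increase with λ
    lower = ws[lams <= 1.0]  # must decrease toward λ = 1
    if np.any(np.diff(upper) < -tol) or np.any(np.diff(lower) > tol):
        raise ValueError(f"{mat.name}: strain energy decreases away from identity")


# ---------------------------------------------------------------------------
# vectorized element-level kinetics used by the FE solver
#
# Thin-layer (generalized plane strain) kinematics: the in-plane deformation
# gradient Fp (…, 2, 2) is augmented with an imposed axial stretch lz, so
# F = blockdiag(Fp, lz).


def energy_and_piola_2d(
    Fp: np.ndarray,
    lz: float,
    params: dict[str, np.ndarray],
    nc: np.ndarray,
    volumetric: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Energy density and in-plane first Piola stress, vectorized.

    Parameters
    ----------
    Fp:
        (..., 2, 2) in-plane deformation gradients.
    lz:
        imposed axial stretch.
    params:
        per-point arrays ``c1, c2, D1, D2, K1, K2, kappa`` broadcastable to
        the leading shape of ``Fp``.
    nc:
        (..., 2) reference circumferential fiber directions (unit).
    volumetric:
        include the κ/2 (J−1)² penalty (switched off when the penalty is
        integrated at a separate reduced quadrature point).

    Returns
    -------
    W (...,), Pp (..., 2, 2)
    """
    c1, c2 = params["c1"], params["c2"]
    D1, D2 = params["D1"], params["D2"]
    K1, K2 = params["K1"], params["K2"]
    kappa = params["kappa"]

    Cp = np.swapaxes(Fp, -1, -2) @ Fp
    trCp = Cp[..., 0, 0] + Cp[..., 1, 1]
    i1 = trCp + lz**2
    trCp2 = (Cp * np.swapaxes(Cp, -1, -2)).sum(axis=(-2, -1))
    i2 = 0.5 * (i1**2 - (trCp2 + lz**4))
    detFp = Fp[..., 0, 0] * Fp[..., 1, 1] - Fp[..., 0, 1] * Fp[..., 1, 0]
    J = detFp * lz
    if np.any(J <= 0):
        raise FloatingPointError("element inversion: J <= 0")

    jm23 = J ** (-2.0 / 3.0)
    i1b = i1 * jm23
    i2b = i2 * jm23**2
    expo = np.exp(D2 * (i1b - 3.0))
    W = c1 * (i1b - 3.0) + c2 * (i2b - 3.0) + D1 * (expo - 1.0)
    w1 = c1 + D1 * D2 * expo

    Cn = (Cp @ nc[..., None])[..., 0]
    i4 = (nc * Cn).sum(axis=-1)
    i4b = i4 * jm23
    g = np.exp(K2 * (i4b - 1.0) ** 2)
    W = W + K1 / K2 * (g - 1.0)
    w4 = 2.0 * K1 * (i4b - 1.0) * g

    # in-plane C inverse, analytic 2x2
    det = Cp[..., 0, 0] * Cp[..., 1, 1] - Cp[..., 0, 1] * Cp[..., 1, 0]
    Cinv = np.empty_like(Cp)
    Cinv[..., 0, 0] = Cp[..., 1, 1]
    Cinv[..., 1, 1] = Cp[..., 0, 0]
    Cinv[..., 0, 1] = -Cp[..., 0, 1]
    Cinv[..., 1, 0] = -Cp[..., 1, 0]
    Cinv /= det[..., None, None]

    eye = np.broadcast_to(np.eye(2), Cp.shape)
    nn_ = nc[..., :, None] * nc[..., None, :]
    Sp = 2.0 * (
        (w1 * jm23)[..., None, None] * (eye - (i1 / 3.0)[..., None, None] * Cinv)
        + (c2 * jm23**2)[..., None, None]
        * (i1[..., None, None] * eye - Cp - (2.0 * i2 / 3.0)[..., None, None] * Cinv)
        + (w4 * jm23)[..., None, None] * (nn_ - (i4 / 3.0)[..., None, None] * Cinv)
    )
    if volumetric:
        W = W + 0.5 * kappa * (J - 1.0) ** 2
        Sp = Sp + (kappa * (J - 1.0) * J)[..., None, None] * Cinv
    Pp = Fp @ Sp
    return W, Pp


def cauchy_2d(Fp: np.ndarray, lz: float, params: dict[str, np.ndarray], nc: np.ndarray):
    """Full 3D Cauchy stress and Green strain from in-plane kinematics.

    Returns (sigma (..., 3, 3), E (..., 3, 3)); the out-of-plane normal
    stress follows from the plane-stretch kinematics and the volumetric
    penalty.
    """
    c1, c2 = params["c1"], params["c2"]
    D1, D2 = params["D1"], params["D2"]
    K1, K2 = params["K1"], params["K2"]
    kappa = params["kappa"]

    lead = Fp.shape[:-2]
    F = np.zeros(lead + (3, 3))
    F[..., :2, :2] = Fp
    F[..., 2, 2] = lz
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = np.linalg.inv(C)
    i1 = np.trace(C, axis1=-2, axis2=-1)
    i2 = 0.5 * (i1**2 - np.einsum("...ij,...ji->...", C, C))
    J = np.linalg.det(F)
    jm23 = J ** (-2.0 / 3.0)
    i1b = i1 * jm23
    expo = np.exp(D2 * (i1b - 3.0))
    w1 = c1 + D1 * D2 * expo
    n3 = np.zeros(lead + (3,))
    n3[..., :2] = nc
    i4 = np.einsum("...i,...ij,...j->...", n3, C, n3)
    i4b = i4 * jm23
    w4 = 2.0 * K1 * (i4b - 1.0) * np.exp(K2 * (i4b - 1.0) ** 2)
    eye = np.broadcast_to(np.eye(3), C.shape)
    S = 2.0 * (
        (w1 * jm23)[..., None, None] * (eye - (i1 / 3.0)[..., None, None] * Cinv)
        + (c2 * jm23**2)[..., None, None]
        * (i1[..., None, None] * eye - C - (2.0 * i2 / 3.0)[..., None, None] * Cinv)
        + (w4 * jm23)[..., None, None]
        * (np.einsum("...i,...j->...ij", n3, n3) - (i4 / 3.0)[..., None, None] * Cinv)
    )
    S = S + (kappa * (J - 1.0) * J)[..., None, None] * Cinv
    sigma = np.einsum("...ik,...kl,...jl->...ij", F, S, F) / J[..., None, None]
    E = 0.5 * (C - eye)
    return sigma, E
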