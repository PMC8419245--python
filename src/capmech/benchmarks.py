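"""Semi-analytic benchmarks for the thin-layer FE solver.

Incompressible inflation of a thick-walled cylinder (plane cross-section,
fixed axial stretch λz) admits a one-dimensional reduction: with
incompressibility, the deformed radius field is

    r(R)² = ri² + (R² − Ri²) / λz ,   λθ = r/R,  λr = 1/(λθ λz),

and radial equilibrium integrates to

    p = ∫_ri^ro (σθθ − σrr) dr / r ,  σθθ − σrr = λθ ∂Ŵ/∂λθ − λr ∂Ŵ/∂λr,

where Ŵ(λr, λθ, λz) is the strain-energy density on the principal-stretch
diagonal.  The stress profile follows by quadrature:

    σrr(r) = −p + ∫_ri^r (σθθ − σrr) dr'/r' ,  σθθ = σrr + (λθŴθ − λrŴr).

These formulas are evaluated here by dense numerical quadrature, fully
independent of the FE discretization, and serve as the oracle for the
hoop-stress profile.  A linear-elastic Lamé solution provides the
small-pressure limit.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from capmech.materials import DeformationState, MaterialParams, strain_energy


def _w_hat(mat: MaterialParams, lr: float, lt: float, lz: float) -> float:
    F = np.diag([lr, lt, lz])
    # circumferential fiber direction, relevant only for anisotropic sets
    return strain_energy(
        DeformationState(F), mat, nc=np.array([0.0, 1.0, 0.0]), include_volumetric=False
    )


def _stress_diff(mat: MaterialParams, lt: np.ndarray, lz: float, h: float = 1e-6) -> np.ndarray:
    """σθθ − σrr on the incompressible diagonal, by numeric differentiation.

    On the incompressible path λr = 1/(λθ λz), the chain-rule derivative
    dŴ/dλθ along the path equals (λθ Ŵθ − λr Ŵr)/λθ, so
    σθθ − σrr = λθ · dŴ/dλθ|path.
    """
    lt = np.asarray(lt, float)
    out = np.empty_like(lt)
    for i, t in enumerate(lt.ravel()):
        dw = (
            _w_hat(mat, 1.0 / ((t + h) * lz), t + h, lz)
            - _w_hat(mat, 1.0 / ((t - h) * lz), t - h, lz)
        ) / (2 * h)
        out.ravel()[i] = t * dw
    return out


def tube_pressure(
    mat: MaterialParams, Ri: float, Ro: float, ri: float, lz: float = 1.0, n: int = 2000
) -> float:
    """Internal pressure (kPa) producing deformed inner radius ``ri``."""
    R = np.linspace(Ri, Ro, n)
    r = np.sqrt(ri**2 + (R**2 - Ri**2) / lz)
    lt = r / R
    sd = _stress_diff(mat, lt, lz)
    return float(np.trapezoid(sd / r, r))


def tube_inner_radius(
    mat: MaterialParams, Ri: float, Ro: float, pressure: float, lz: float = 1.0
) -> float:
    """Deformed inner radius at a given internal pressure, by root finding."""
    if pressure == 0:
        # zero pressure with axial stretch still contracts the section
        lo, hi = 0.5 * Ri, 1.5 * Ri
    else:
        lo, hi = 0.8 * Ri, 3.0 * Ri
    f = lambda ri: tube_pressure(mat, Ri, Ro, ri, lz) - pressure
    return float(brentq(f, lo, hi, xtol=1e-10))


def tube_hoop_stress_profile(
    mat: MaterialParams, Ri: float, Ro: float, pressure: float, lz: float = 1.0, n: int = 2000
):
    """Deformed radii and hoop (circumferential) Cauchy stress profile.

    Returns (r, sigma_hoop, sigma_radial) arrays across the wall for the
    incompressible tube at the given pressure.
    """
    ri = tube_inner_radius(mat, Ri, Ro, pressure, lz)
    R = np.linspace(Ri, Ro, n)
    r = np.sqrt(ri**2 + (R**2 - Ri**2) / lz)
    lt = r / R
    sd = _stress_diff(mat, lt, lz)
    srr = -pressure + cumulative_trapezoid(sd / r, r, initial=0.0)
    stt = srr + sd
    return r, stt, srr


def lame_radial_displacement(
    mu: float, Ri: float, Ro: float, pressure: float, r: np.ndarray
) -> np.ndarray:
    """Incompressible plane-strain Lamé displacement u(r) at small pressure.

    u(r) = p Ri² Ro² / (2 μ (Ro² − Ri²) r) — the linear-elastic limit used
    to check the FE solver at vanishing load.
    """
    r = np.asarray(r, float)
    return pressure * Ri**2 * Ro**2 / (2.0 * mu * (Ro**2 - Ri**2) * r)


def small_strain_shear_modulus(mat: MaterialParams) -> float:
    """Equivalent shear modulus 2(c1 + c2 + D1 D2) at the identity."""
    return 2.0 * (mat.c1 + mat.c2 + mat.D1 * mat.D2)
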