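"""Thin-layer FE: oracle agreement, limits, aggregates, convergence."""

import numpy as np
import pytest
import scipy.interpolate as si

from capmech.benchmarks import (
    lame_radial_displacement,
    small_strain_shear_modulus,
    tube_hoop_stress_profile,
)
from capmech.contours import SliceContour
from capmech.femesh import build_mesh
from capmech.geometry import CapProfile, build_cap_profile
from capmech.solver import (
    ThinLayerModel,
    cap_aggregates,
    mesh_convergence,
    nodal_hoop_stress,
    stress_strain_fields,
    StressStrainResult,
)
from tests.conftest import circle, make_annulus

ORACLE_PRESSURES = (4.0, 9.3, 16.0)


@pytest.fixture(scope="module")
def annulus_mesh(annulus):
    return build_mesh(annulus, target_density=1.0)


@pytest.fixture(scope="module")
def oracle_solutions(annulus_mesh, bench_materials):
    out = {}
    for p in ORACLE_PRESSURES:
        model = ThinLayerModel(annulus_mesh, bench_materials, axial_stretch=1.05)
        out[p] = (model, model.solve(p))
    return out


class TestInflationOracle:
    @pytest.mark.parametrize("pressure", ORACLE_PRESSURES)
    def test_hoop_stress_within_5pct_of_tube_oracle(
        self, oracle_solutions, annulus_mesh, bench_material, pressure
    ):
        model, u = oracle_solutions[pressure]
        hoop = nodal_hoop_stress(model, u)
        r_def = np.hypot(*(annulus_mesh.nodes + u).T)
        r, stt, _ = tube_hoop_stress_profile(bench_material, 1.5, 2.5, pressure, 1.05)
        f = si.interp1d(r, stt, fill_value="extrapolate")
        rel = np.abs((hoop - f(r_def)) / f(r_def))
        assert rel.max() < 0.05

    def test_deformed_inner_radius_matches_oracle(
        self, oracle_solutions, annulus_mesh, bench_material
    ):
        model, u = oracle_solutions[9.3]
        r_fe = np.hypot(*(annulus_mesh.nodes + u).T).min()
        r_or, _, _ = tube_hoop_stress_profile(bench_material, 1.5, 2.5, 9.3, 1.05)
        assert r_fe == pytest.approx(r_or.min(), rel=0.01)


class TestLimits:
    def test_zero_load_zero_displacement(self, annulus_mesh, bench_materials):
        model = ThinLayerModel(annulus_mesh, bench_materials, axial_stretch=1.0)
        u = model.solve(0.0)
        assert np.abs(u).max() == 0.0
        res = stress_strain_fields(model, u, 0.0)
        assert np.abs(res.nodal_strain).max() < 1e-12
        assert np.abs(res.nodal_stress).max() < 1e-9

    def test_small_pressure_matches_lame(self, annulus_mesh, bench_materials, bench_material):
        p = 0.1
        model = ThinLayerModel(annulus_mesh, bench_materials, axial_stretch=1.0)
        u = model.solve(p)
        r0 = np.hypot(*annulus_mesh.nodes.T)
        ur = (u * (annulus_mesh.nodes / r0[:, None])).sum(axis=1)
        mu = small_strain_shear_modulus(bench_material)
        expected = lame_radial_displacement(mu, 1.5, 2.5, p, r0)
        assert np.abs((ur - expected) / expected).max() < 0.05

    def test_negative_pressure_rejected(self, annulus_mesh, bench_materials):
        model = ThinLayerModel(annulus_mesh, bench_materials)
        with pytest.raises(ValueError):
            model.solve(-1.0)


def crescent_slice(cap: float, r_lumen: float = 1.5, wall: float = 1.0):
    """Annulus with a lipid crescent under a cap of the given thickness."""
    cs = make_annulus(r_lumen, r_lumen + wall)
    theta = np.linspace(-np.pi / 3, np.pi / 3, 40)
    inner_r = r_lumen + cap
    outer_r = r_lumen + min(cap + 0.45 * wall, 0.9 * wall)
    inner = np.column_stack([inner_r * np.cos(theta), inner_r * np.sin(theta)])
    outer = np.column_stack([outer_r * np.cos(theta[::-1]), outer_r * np.sin(theta[::-1])])
    cs["lipid"] = SliceContour("P", "S", "baseline", "IO", "lipid", np.vstack([inner, outer]))
    return cs


class TestCapAggregates:
    def test_uniform_field_max_equals_mean(self, annulus_mesh):
        profile = CapProfile(
            lumen_points=circle(1.5, 100),
            outwall_points=circle(2.5, 100),
            wall_thickness=np.ones(100),
            cap_thickness=np.full(100, 0.2),
            quarter_index=np.repeat([1, 2, 3, 4], 25),
        )
        res = StressStrainResult(
            mesh=annulus_mesh,
            displacement=np.zeros_like(annulus_mesh.nodes),
            nodal_stress=np.full(annulus_mesh.n_nodes, 42.0),
            nodal_strain=np.full(annulus_mesh.n_nodes, 0.1),
            pressure_kpa=9.0,
            axial_stretch=1.05,
        )
        agg = cap_aggregates(res, profile)
        assert agg.MaxCapS == agg.MeanCapS == 42.0
        assert agg.MaxCapSn == pytest.approx(0.1)
        assert agg.MeanCapSn == pytest.approx(agg.MaxCapSn)

    def test_no_cap_points_returns_none(self, annulus_mesh):
        profile = CapProfile(
            lumen_points=circle(1.5, 100),
            outwall_points=circle(2.5, 100),
            wall_thickness=np.ones(100),
            cap_thickness=np.full(100, np.nan),
            quarter_index=np.repeat([1, 2, 3, 4], 25),
        )
        res = StressStrainResult(
            mesh=annulus_mesh,
            displacement=np.zeros_like(annulus_mesh.nodes),
            nodal_stress=np.zeros(annulus_mesh.n_nodes),
            nodal_strain=np.zeros(annulus_mesh.n_nodes),
            pressure_kpa=9.0,
            axial_stretch=1.05,
        )
        assert cap_aggregates(res, profile) is None

    def test_max_at_least_mean_on_solved_slices(self, small_cohort):
        from capmech.cohort import MMHG_TO_KPA
        from capmech.pipeline import MechanicsConfig, slice_mechanics

        cfg = MechanicsConfig(mesh_density=0.4, calibrate=False)
        for s in small_cohort.slices[:3]:
            cs = s.sets[("baseline", "IO")]
            mech = slice_mechanics(cs, 9.0, config=cfg)
            agg = mech.aggregates
            assert agg.MaxCapS >= agg.MeanCapS
            assert agg.MaxCapSn >= agg.MeanCapSn

    def test_thinner_cap_raises_max_cap_stress(self):
        cfg_p = 9.3
        from capmech.pipeline import MechanicsConfig, slice_mechanics

        cfg = MechanicsConfig(mesh_density=0.6, calibrate=False)
        thick = slice_mechanics(crescent_slice(cap=0.40), cfg_p, config=cfg)
        thin = slice_mechanics(crescent_slice(cap=0.20), cfg_p, config=cfg)
        assert thin.aggregates.MaxCapS > thick.aggregates.MaxCapS


class TestMeshConvergence:
    def test_terminates_under_2pct_rule(self, bench_materials):
        cs = crescent_slice(cap=0.3)
        profile = build_cap_profile(cs)

        def build_model(density):
            return ThinLayerModel(build_mesh(cs, target_density=density), axial_stretch=1.05)

        result, agg, trace = mesh_convergence(build_model, 9.3, profile, density0=0.5)
        assert len(trace) >= 2
        (d1, q1), (d2, q2) = trace[-2], trace[-1]
        assert abs(q2 - q1) <= 0.02 * abs(q2)  # stopping rule holds by construction
        assert d2 == pytest.approx(d1 * 1.1)

    def test_fine_start_terminates_quickly(self):
        cs = crescent_slice(cap=0.3)
        profile = build_cap_profile(cs)

        def build_model(density):
            return ThinLayerModel(build_mesh(cs, target_density=density), axial_stretch=1.05)

        _, _, trace = mesh_convergence(build_model, 9.3, profile, density0=1.2)
        assert len(trace) <= 3
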