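"""Synthetic cohort generator: determinism, structure, and the planted signal."""

import numpy as np
import pandas as pd
import pytest

from capmech.cohort import CohortConfig, degrade_to_ivus, generate_cohort, quantize_cap
from capmech.contours import contour_sets_to_frame, validate_contour_set
from capmech.geometry import build_cap_profile


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = dict(n_patients=2, slices_per_patient=(2, 2))
        a = generate_cohort(CohortConfig(seed=5, **cfg))
        b = generate_cohort(CohortConfig(seed=5, **cfg))
        fa = contour_sets_to_frame(a.contour_sets())
        fb = contour_sets_to_frame(b.contour_sets())
        pd.testing.assert_frame_equal(fa, fb)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_different_seed_differs(self):
        cfg = dict(n_patients=1, slices_per_patient=(2, 2))
        a = generate_cohort(CohortConfig(seed=5, **cfg))
        b = generate_cohort(CohortConfig(seed=6, **cfg))
        assert not np.allclose(
            a.slices[0].sets[("baseline", "IO")]["lumen"].points,
            b.slices[0].sets[("baseline", "IO")]["lumen"].points,
        )


class TestCohortStructure:
    def test_study_scale_slice_count(self):
        """9 patients at ~13 slices each give on the order of 114 lipid slices."""
        cohort = generate_cohort(CohortConfig(seed=1))
        assert 9 * 12 <= len(cohort.slices) <= 9 * 14
        assert abs(len(cohort.slices) - 114) <= 12
        s = cohort.slices[0]
        assert set(s.sets) == {
            ("baseline", "IO"),
            ("baseline", "IVUS"),
            ("follow_up", "IO"),
            ("follow_up", "IVUS"),
        }

    def test_all_polygons_pass_invariants(self, small_cohort):
        for s in small_cohort.slices:
            for cs in s.sets.values():
                validate_contour_set(cs)

    def test_no_signal_no_noise_zero_delta(self):
        cfg = CohortConfig(
            seed=2,
            n_patients=2,
            slices_per_patient=(3, 3),
            progression_coefficients=(0, 0, 0, 0),
            progression_noise_sd_mm=0.0,
        )
        cohort = generate_cohort(cfg)
        assert np.allclose(cohort.ground_truth["planted_delta_mincapt_mm"], 0.0)
        for s in cohort.slices:
            bl = build_cap_profile(s.sets[("baseline", "IO")]).cap_values.min()
            fu = build_cap_profile(s.sets[("follow_up", "IO")]).cap_values.min()
            assert fu == pytest.approx(bl, abs=5e-3)

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0).validate()
        with pytest.raises(ValueError):
            CohortConfig(pressure_mmHg=((90, 95), (80, 85))).validate()
        with pytest.raises(ValueError):
            # wall too thin for any lipid: every draw degenerate
            generate_cohort(
                CohortConfig(
                    seed=0,
                    n_patients=1,
                    slices_per_patient=(1, 1),
                    wall_thickness_mm=(0.5, 0.0),
                    cap_thickness_mm=(0.45, 0.45),
                )
            )


class TestIvusDegradation:
    def test_identity_when_no_bias_noise_floor(self, one_slice):
        io = one_slice.sets[("baseline", "IO")]
        cfg = CohortConfig(ivus_point_noise_sd_mm=0.0, ivus_resolution_floor_mm=0.0)
        iv = degrade_to_ivus(io, 0.0, cfg, np.random.default_rng(0))
        assert np.allclose(iv["lumen"].points, io["lumen"].points)
        assert np.allclose(iv["outwall"].points, io["outwall"].points)
        io_min = build_cap_profile(io).cap_values.min()
        iv_min = build_cap_profile(iv).cap_values.min()
        assert iv_min == pytest.approx(io_min, abs=2e-3)

    def test_negative_bias_halves_min_cap_before_floor(self, one_slice):
        io = one_slice.sets[("baseline", "IO")]
        cfg = CohortConfig(ivus_point_noise_sd_mm=0.0, ivus_resolution_floor_mm=0.0)
        iv = degrade_to_ivus(io, -0.5, cfg, np.random.default_rng(0))
        io_min = build_cap_profile(io).cap_values.min()
        iv_min = build_cap_profile(iv).cap_values.min()
        assert iv_min == pytest.approx(0.5 * io_min, rel=0.08)

    def test_lumen_outwall_shared_between_modalities(self, small_cohort):
        for s in small_cohort.slices:
            for tp in ("baseline", "follow_up"):
                io, iv = s.sets[(tp, "IO")], s.sets[(tp, "IVUS")]
                assert np.array_equal(io["lumen"].points, iv["lumen"].points)
                assert np.array_equal(io["outwall"].points, iv["outwall"].points)
                assert iv["lipid"].modality == "IVUS"

    def test_quantization(self):
        assert np.allclose(quantize_cap(np.array([0.16]), 0.15), 0.15)
        assert np.allclose(quantize_cap(np.array([0.02]), 0.15), 0.075)
        assert np.allclose(quantize_cap(np.array([0.3]), 0.0), 0.3)


class TestPlantedSignal:
    def test_regression_recovers_coefficient_signs(self):
        """At n ≥ 500 slices an OLS of ΔMinCapT on the planted predictors
        recovers the sign of every nonzero planted effect."""
        cfg = CohortConfig(seed=13, n_patients=40, slices_per_patient=(13, 13))
        cohort = generate_cohort(cfg)
        gt = cohort.ground_truth
        assert len(gt) >= 500
        rows = []
        from capmech.cohort import MMHG_TO_KPA
        from capmech.geometry import morpho_features

        pressures = cohort.pressures.set_index("patient_id")["diastolic_mmHg"]
        for s in cohort.slices:
            cs = s.sets[("baseline", "IO")]
            prof = build_cap_profile(cs)
            f = morpho_features(cs, prof)
            p_kpa = float(pressures.loc[s.patient_id]) * MMHG_TO_KPA
            proxy = p_kpa * np.sqrt(f.LA / np.pi) / f.MinCapT
            rows.append((f.PA, f.MinCapT, proxy, f.PB))
        X = np.asarray(rows)
        z = (X - X.mean(0)) / X.std(0)
        y = gt["planted_delta_mincapt_mm"].to_numpy()
        beta = np.linalg.lstsq(np.column_stack([np.ones(len(z)), z]), y, rcond=None)[0][1:]
        assert np.all(np.sign(beta) == np.sign(cfg.progression_coefficients))
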