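"""Four-Quarter Even-Spacing resampling, cap profiles, and error arithmetic."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from capmech.contours import SliceContour
from capmech.geometry import (
    build_cap_profile,
    morpho_features,
    percent_error,
    perimeter,
    resample_lumen,
    summarize,
)
from tests.conftest import circle, make_annulus


def arc_gaps(points):
    d = np.roll(points, -1, axis=0) - points
    return np.hypot(d[:, 0], d[:, 1])


class TestResampleLumen:
    def test_unit_circle_equal_arc_gaps(self):
        pts, quarter = resample_lumen(circle(1.0, 256))
        gaps = arc_gaps(pts)
        assert pts.shape == (100, 2)
        assert np.allclose(gaps, gaps.mean(), rtol=2e-3)
        assert np.array_equal(np.sort(np.unique(quarter)), [1, 2, 3, 4])
        assert np.all(np.bincount(quarter)[1:] == 25)

    def test_perimeter_conserved(self):
        rng = np.random.default_rng(4)
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = 1.5 + 0.2 * np.cos(2 * theta + rng.uniform(0, np.pi)) + 0.1 * np.cos(3 * theta)
        contour = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        pts, _ = resample_lumen(contour)
        # the 100-gon inscribed in the contour reproduces its perimeter
        assert perimeter(pts) == pytest.approx(perimeter(contour), rel=2e-3)

    def test_ellipse_quarter_arcs_match_quadrature(self):
        """Quarter arc-length totals vs dense numeric quadrature (oracle)."""
        a, b = 2.0, 1.0
        t = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        ellipse = np.column_stack([a * np.cos(t), b * np.sin(t)])
        pts, quarter = resample_lumen(ellipse)
        # oracle: dense arc-length integration of each principal-axis quadrant
        td = np.linspace(0, np.pi / 2, 200001)
        integrand = np.hypot(a * np.sin(td), b * np.cos(td))
        quadrant_len = np.trapezoid(integrand, td)
        for q in (1, 2, 3, 4):
            sel = pts[quarter == q]
            # chord length through the quarter, closing at the next anchor
            nxt = pts[quarter == (q % 4 + 1)][0]
            ql = np.hypot(*np.diff(np.vstack([sel, nxt]), axis=0).T).sum()
            assert ql == pytest.approx(quadrant_len, rel=5e-3)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            resample_lumen(np.zeros((30, 2)))


class TestCapProfile:
    def test_concentric_no_lipid(self, annulus):
        prof = build_cap_profile(annulus)
        assert np.allclose(prof.wall_thickness, 1.0, atol=5e-3)
        assert not prof.cap_defined.any()

    def test_lipid_arc_cap_thickness(self):
        """Lipid inner edge at r=1.7 over a 90° arc: cap 0.2 mm on ~25 points."""
        cs = make_annulus()
        theta = np.linspace(-np.pi / 4, np.pi / 4, 30)
        inner = np.column_stack([1.7 * np.cos(theta), 1.7 * np.sin(theta)])
        outer = np.column_stack([2.2 * np.cos(theta[::-1]), 2.2 * np.sin(theta[::-1])])
        cs["lipid"] = SliceContour("P", "S", "baseline", "IO", "lipid", np.vstack([inner, outer]))
        prof = build_cap_profile(cs)
        n_cap = prof.cap_defined.sum()
        assert 20 <= n_cap <= 30
        assert np.allclose(prof.cap_thickness[prof.cap_defined], 0.2, atol=0.01)

    def test_min_cap_matches_dense_ray_casting(self, small_cohort):
        """MinCapT vs a brute-force ray-casting oracle within one step."""
        cs = small_cohort.slices[0].sets[("baseline", "IO")]
        prof = build_cap_profile(cs)
        lumen = Polygon(cs["lumen"].points)
        lipid_ring = LineString(
            np.vstack([cs["lipid"].points, cs["lipid"].points[:1]])
        )
        c = np.array(lumen.centroid.coords[0])
        dists = []
        for th in np.linspace(0, 2 * np.pi, 10000, endpoint=False):
            ray = LineString([c, c + 10.0 * np.array([np.cos(th), np.sin(th)])])
            hit = ray.intersection(lipid_ring)
            if hit.is_empty:
                continue
            lum_hit = ray.intersection(lumen.exterior)
            pts = [hit] if hit.geom_type == "Point" else list(hit.geoms)
            lpts = [lum_hit] if lum_hit.geom_type == "Point" else list(lum_hit.geoms)
            d_lip = min(p.distance(Polygon(cs["lumen"].points).exterior) for p in pts)
            dists.append(d_lip)
        oracle_min = min(dists)
        step = perimeter(prof.lumen_points) / 100
        assert prof.cap_values.min() == pytest.approx(oracle_min, abs=step)

    def test_thinning_lipid_never_increases_mincapt(self, small_cohort):
        cs = dict(small_cohort.slices[1].sets[("baseline", "IO")])
        base = build_cap_profile(cs).cap_values.min()
        lumen = Polygon(cs["lumen"].points)
        c = np.array(lumen.centroid.coords[0])
        pts = cs["lipid"].points
        # pull every lipid vertex 10% of its lumen clearance toward the lumen
        shrunk = c + (pts - c) * 0.97
        cs["lipid"] = cs["lipid"].with_points(shrunk)
        thinner = build_cap_profile(cs).cap_values.min()
        assert thinner <= base + 1e-9


class TestMorphoFeatures:
    def test_concentric_closed_form(self, annulus):
        f = morpho_features(annulus)
        assert f.LA == pytest.approx(np.pi * 1.5**2, rel=2e-3)
        assert f.PA == pytest.approx(np.pi * (2.5**2 - 1.5**2), rel=2e-3)
        assert f.PB == pytest.approx(1 - 1.5**2 / 2.5**2, rel=2e-3)  # = 0.64
        assert f.MinCapT is None and not f.has_cap

    def test_constant_cap(self):
        cs = make_annulus()
        theta = np.linspace(-np.pi / 3, np.pi / 3, 40)
        inner = np.column_stack([1.7 * np.cos(theta), 1.7 * np.sin(theta)])
        outer = np.column_stack([2.1 * np.cos(theta[::-1]), 2.1 * np.sin(theta[::-1])])
        cs["lipid"] = SliceContour("P", "S", "baseline", "IO", "lipid", np.vstack([inner, outer]))
        f = morpho_features(cs)
        assert f.MinCapT == pytest.approx(0.2, abs=0.01)
        assert f.MeanCapT == pytest.approx(0.2, abs=0.01)
        assert f.MinCapT <= f.MeanCapT


class TestErrorArithmetic:
    @pytest.mark.parametrize(
        "io,ivus,expected",
        [
            (0.162, 0.195, 20.37),  # printed cap-thickness cell
            (48.77, 70.35, 44.25),  # printed cap-stress cell
            (1.234, 1.234, 0.0),
        ],
    )
    def test_percent_error_values(self, io, ivus, expected):
        assert percent_error(io, ivus) == pytest.approx(expected, abs=0.005)

    def test_percent_error_exact_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.uniform(0.1, 5, 2)
            assert percent_error(a, b) == pytest.approx(100 * (b / a - 1), rel=1e-12)

    def test_zero_gold_standard_rejected(self):
        with pytest.raises(ValueError):
            percent_error(0.0, 1.0)

    def test_summarize_printed_row(self):
        errors = [20.37, -21.49, 4.80, -57.41, -58.11, -56.48, -20.44, -2.36, 4.82]
        mx, mn, mean, sd = summarize(errors)
        assert (mx, mn) == (20.37, -58.11)
        assert mean == pytest.approx(-20.70, abs=0.005)
        assert sd == pytest.approx(30.32, abs=0.005)  # sample SD (n−1)

    def test_summarize_constant_and_short(self):
        assert summarize([3.0, 3.0, 3.0])[3] == 0.0
        assert np.isnan(summarize([1.0])[3])
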