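"""Convex hulls, reflection, arc-length averaging and shape metrics."""
import numpy as np
import pytest
import shapely
import shapely.geometry as sgeom
from hypothesis import given, settings, strategies as st

from fbos.foot import FootFrame
from fbos.model import (FBOSPolygon, GroupTemplate, METRIC, NORMALIZED,
                        average_polygons, convex_hull, fbos_metrics,
                        make_group_template, polygon_area, reflect_ml,
                        resample_arclength, scale_template)

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _rect_frame(L=0.30, W=0.10):
    """Frame whose footprint hexagon is a degenerate L x W rectangle."""
    marker_foot = {
        "heel": np.array([0.0, 0.0]),
        "lat_ankle": np.array([-W / 2, 0.0]),
        "mtp5": np.array([-W / 2, L]),
        "toe_tip": np.array([0.0, L]),
        "mtp1": np.array([W / 2, L]),
        "med_ankle": np.array([W / 2, 0.0]),
    }
    return FootFrame(side="left", origin=np.zeros(2),
                     anterior=np.array([0.0, 1.0]),
                     lateral=np.array([1.0, 0.0]),
                     foot_length=L, foot_width=W, marker_foot=marker_foot)


class TestHull:
    def test_square_with_interior_points(self, rng):
        pts = np.vstack([SQUARE, rng.uniform(0.05, 0.95, size=(200, 2))])
        hull = convex_hull(pts)
        assert hull.area == pytest.approx(1.0, abs=1e-12)
        assert len(hull.vertices) == 4

    def test_disc_area_converges(self, rng):
        r = 0.1
        areas = []
        for n in (100, 1000, 20000):
            ang = rng.uniform(0, 2 * np.pi, n)
            rad = r * np.sqrt(rng.uniform(0, 1, n))
            pts = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
            areas.append(convex_hull(pts).area)
        target = np.pi * r * r
        assert all(a <= target + 1e-12 for a in areas)
        assert areas[-1] > 0.98 * target
        assert areas[0] < areas[2]

    def test_idempotence(self, rng):
        pts = rng.normal(size=(50, 2))
        h1 = convex_hull(pts)
        h2 = convex_hull(h1.vertices)
        assert shapely.equals_exact(h1.as_shapely(), h2.as_shapely(),
                                    tolerance=1e-12) or np.allclose(
            np.sort(h1.vertices, axis=0), np.sort(h2.vertices, axis=0))

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            convex_hull(np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]]))
        with pytest.raises(ValueError):
            convex_hull(np.array([[0, 0], [1, 1.0]]))


class TestArea:
    def test_unit_square(self):
        assert polygon_area(SQUARE) == 1.0

    def test_3_4_5_triangle(self):
        assert polygon_area(np.array([[0, 0], [3, 0], [0, 4.0]])) == 6.0

    def test_orientation_and_start_invariance(self):
        v = np.array([[0, 0], [2, 0], [2.5, 1.0], [1.0, 2.0], [-0.5, 1.0]])
        a = polygon_area(v)
        assert polygon_area(v[::-1]) == a
        assert polygon_area(np.roll(v, 2, axis=0)) == pytest.approx(a)

    def test_monte_carlo_oracle(self, rng):
        v = convex_hull(rng.normal(size=(25, 2))).vertices
        poly = sgeom.Polygon(v)
        lo, hi = v.min(axis=0), v.max(axis=0)
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        frac = np.mean(shapely.contains_xy(poly, pts[:, 0], pts[:, 1]))
        mc = frac * np.prod(hi - lo)
        assert polygon_area(v) == pytest.approx(mc, rel=0.005)


class TestReflect:
    def test_symmetric_polygon_fixed(self):
        sym = FBOSPolygon(np.array([[-1, 0], [1, 0], [1, 1], [-1, 1.0]]))
        r = reflect_ml(sym)
        assert sgeom.Polygon(r.vertices).equals(sgeom.Polygon(sym.vertices))

    def test_involution_and_area(self, rng):
        poly = convex_hull(rng.normal(size=(20, 2)))
        r2 = reflect_ml(reflect_ml(poly))
        assert sgeom.Polygon(r2.vertices).equals(
            sgeom.Polygon(poly.vertices))
        assert reflect_ml(poly).area == pytest.approx(poly.area, abs=1e-15)

    def test_side_provenance_swaps(self):
        poly = FBOSPolygon(SQUARE, side="right")
        assert reflect_ml(poly).side == "left"


class TestResample:
    def test_square_arc_positions(self):
        # centroid (0.5, 0.5); +y ray hits (0.5, 1) on the top edge;
        # perimeter 4, so n=8 gives points every 0.5 of arc length:
        # top-mid, corners and side-mids in CCW order
        out = resample_arclength(FBOSPolygon(SQUARE), 8)
        expected = np.array([[0.5, 1], [0, 1], [0, 0.5], [0, 0],
                             [0.5, 0], [1, 0], [1, 0.5], [1, 1.0]])
        assert out == pytest.approx(expected, abs=1e-12)

    def test_perimeter_refinement(self):
        poly = convex_hull(np.random.default_rng(3).normal(size=(12, 2)))
        errs = []
        for n in (16, 64, 512):
            ring = resample_arclength(poly, n)
            per = np.linalg.norm(
                np.diff(np.vstack([ring, ring[:1]]), axis=0), axis=1).sum()
            assert per <= poly.perimeter + 1e-12  # chords cut corners
            errs.append(poly.perimeter - per)
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 0.01 * poly.perimeter

    def test_storage_order_invariance(self):
        a = resample_arclength(FBOSPolygon(SQUARE), 16)
        b = resample_arclength(FBOSPolygon(np.roll(SQUARE, 2, axis=0)), 16)
        assert a == pytest.approx(b, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_arclength(FBOSPolygon(SQUARE), 4)


class TestAverage:
    def test_identity_on_duplicates(self):
        poly = FBOSPolygon(SQUARE)
        avg, disp = average_polygons([poly] * 5, n_points=64)
        assert avg.area == pytest.approx(1.0, rel=1e-6)
        assert np.max(disp) < 1e-12
        assert sgeom.Polygon(avg.vertices).symmetric_difference(
            sgeom.Polygon(SQUARE)).area < 1e-9

    def test_scaled_pair_gives_intermediate(self):
        # square centred on the origin and the same square scaled x2:
        # matched arc-length parameterisation averages to the x1.5 square
        sq = FBOSPolygon(SQUARE - 0.5)
        sq2 = FBOSPolygon((SQUARE - 0.5) * 2.0)
        avg, _ = average_polygons([sq, sq2], n_points=128)
        expect = sgeom.Polygon((SQUARE - 0.5) * 1.5)
        assert avg.area == pytest.approx(expect.area, rel=1e-6)
        assert sgeom.Polygon(avg.vertices).symmetric_difference(
            expect).area < 1e-6

    def test_permutation_invariance(self, rng):
        polys = [convex_hull(rng.normal(size=(15, 2))) for _ in range(4)]
        a1, _ = average_polygons(polys, n_points=64)
        a2, _ = average_polygons(polys[::-1], n_points=64)
        assert sgeom.Polygon(a1.vertices).symmetric_difference(
            sgeom.Polygon(a2.vertices)).area < 1e-12

    def test_mixed_units_rejected(self):
        with pytest.raises(ValueError, match="units"):
            average_polygons([FBOSPolygon(SQUARE, units=METRIC),
                              FBOSPolygon(SQUARE, units=NORMALIZED)])

    def test_bootstrap_dispersion_contracts(self, rng):
        base = convex_hull(rng.normal(size=(30, 2)))

        def replicate():
            jitter = rng.normal(0, 0.05, size=base.vertices.shape)
            return FBOSPolygon(convex_hull(base.vertices + jitter).vertices)

        reps = [replicate() for _ in range(64)]

        def area_sd(k, draws=12):
            areas = []
            for _ in range(draws):
                picks = rng.choice(64, k, replace=False)
                areas.append(average_polygons([reps[j] for j in picks],
                                              64)[0].area)
            return np.std(areas)

        assert area_sd(32) < area_sd(4)


class TestMetrics:
    def test_polygon_equal_to_footprint(self):
        frame = _rect_frame()
        fp_poly = FBOSPolygon(np.array(
            [[-0.05, 0], [0.05, 0], [0.05, 0.30], [-0.05, 0.30]]))
        m = fbos_metrics(fp_poly, frame)
        assert m.area_ratio == pytest.approx(1.0, rel=1e-9)
        assert m.d_toe == pytest.approx(0.0, abs=1e-12)
        assert m.d_heel == pytest.approx(0.0, abs=1e-12)
        assert m.d_lat_ankle == pytest.approx(0.0, abs=1e-12)

    def test_rectangle_band_arithmetic(self):
        frame = _rect_frame(L=0.30, W=0.10)
        band = FBOSPolygon(np.array(
            [[-0.02, 0.05], [0.02, 0.05], [0.02, 0.25], [-0.02, 0.25]]))
        m = fbos_metrics(band, frame)
        assert m.d_heel == pytest.approx(0.05 / 0.30)
        assert m.d_toe == pytest.approx(0.05 / 0.30)
        assert m.norm_length == pytest.approx(0.20 / 0.30)
        assert m.norm_width == pytest.approx(0.04 / 0.10)
        assert m.area_ratio == pytest.approx((0.04 * 0.20) / 0.03)

    def test_outside_footprint_flagged_not_fatal(self):
        frame = _rect_frame()
        big = FBOSPolygon(np.array(
            [[-0.2, -0.1], [0.2, -0.1], [0.2, 0.5], [-0.2, 0.5]]))
        m = fbos_metrics(big, frame)
        assert m.outside_footprint
        assert np.isfinite(m.area_ratio)


class TestScaleTemplate:
    def _template(self, verts):
        return GroupTemplate(group="young",
                             polygon=FBOSPolygon(verts, units=NORMALIZED),
                             dispersion=np.zeros(len(verts)),
                             n_participants=1)

    def test_exact_extent_multiplication(self):
        tpl = self._template(np.array(
            [[-0.25, 0.2], [0.25, 0.2], [0.25, 0.8], [-0.25, 0.8]]))
        poly = scale_template(tpl, foot_length=0.30, foot_width=0.10)
        v = poly.vertices
        assert v[:, 0].max() - v[:, 0].min() == pytest.approx(0.05)
        assert v[:, 1].max() - v[:, 1].min() == pytest.approx(0.18)
        assert poly.units == METRIC

    def test_scale_unscale_identity(self):
        tpl = self._template(np.array(
            [[-0.2, 0.1], [0.3, 0.2], [0.1, 0.9]]))
        poly = scale_template(tpl, 0.27, 0.09)
        back = poly.vertices / np.array([0.09, 0.27])
        assert back == pytest.approx(tpl.polygon.vertices, abs=1e-14)

    def test_toe_margin_in_cm(self):
        # a template whose toe inward distance is 0.2167 of foot length
        # puts the fBOS edge 6.5 cm inside the toe marker of a 30 cm foot
        tpl = self._template(np.array(
            [[-0.2, 0.15], [0.2, 0.15], [0.2, 1 - 0.2167], [-0.2, 1 - 0.2167]]))
        poly = scale_template(tpl, foot_length=0.30, foot_width=0.10)
        toe_margin_cm = (0.30 - poly.vertices[:, 1].max()) * 100
        assert toe_margin_cm == pytest.approx(6.5, abs=0.01)

    def test_right_side_mirrors(self):
        tpl = self._template(np.array([[-0.3, 0.1], [0.1, 0.2], [0.0, 0.8]]))
        left = scale_template(tpl, 0.3, 0.1, side="left")
        right = scale_template(tpl, 0.3, 0.1, side="right")
        assert right.vertices[:, 0].max() == pytest.approx(
            -left.vertices[:, 0].min())


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_hull_contains_all_points_property(seed):
    """Every input point lies in the hull; hull is convex."""
    pts = np.random.default_rng(seed).normal(size=(30, 2))
    hull = convex_hull(pts)
    poly = sgeom.Polygon(hull.vertices).buffer(1e-9)
    assert shapely.contains_xy(poly, pts[:, 0], pts[:, 1]).all()
    assert sgeom.Polygon(hull.vertices).equals(
        sgeom.Polygon(hull.vertices).convex_hull)


def test_group_template_roundtrip_building(rng):
    polys = [FBOSPolygon(convex_hull(rng.normal(size=(12, 2))).vertices,
                         units=NORMALIZED) for _ in range(5)]
    tpl = make_group_template("old", polys, n_points=64)
    assert tpl.n_participants == 5
    assert tpl.polygon.units == NORMALIZED
    assert len(tpl.dispersion) == 64
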