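"""Shape descriptors: boundary chain, perimeter, circularity, solidity,
moment ellipse, Feret diameters, and the field/specimen aggregation."""

import math

import numpy as np
import pytest
from scipy import ndimage

from conftest import rasterize_disk, rasterize_ellipse
from cytocluster import morphometry as mm


def square_mask(side: int, pad: int = 3) -> np.ndarray:
    m = np.zeros((side + 2 * pad, side + 2 * pad), bool)
    m[pad:pad + side, pad:pad + side] = True
    return m


class TestBoundaryTrace:
    def test_single_pixel_degenerate(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        ch = mm.trace_boundary(m)
        assert ch.degenerate and ch.codes.size == 0

    def test_3x3_square_has_8_boundary_pixels(self):
        ch = mm.trace_boundary(square_mask(3))
        assert len(ch.pixels) == 8
        assert ch.closed

    def test_chain_visits_exactly_the_morphological_boundary(self, rng):
        """The traced pixel set equals mask minus its 4-connected erosion."""
        for _ in range(10):
            blob = ndimage.binary_dilation(
                rng.random((24, 24)) < 0.04, iterations=3)
            lab, n = ndimage.label(blob)
            sizes = np.bincount(lab.ravel())[1:]
            big = int(np.argmax(sizes)) + 1
            comp = lab == big
            if comp.sum() < 5:
                continue
            comp = ndimage.binary_fill_holes(comp)
            ch = mm.trace_boundary(comp)
            er = ndimage.binary_erosion(comp, structure=np.array(
                [[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool))
            expected = set(map(tuple, np.argwhere(comp & ~er)))
            assert set(map(tuple, ch.pixels)) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mm.trace_boundary(np.zeros((4, 4), bool))


class TestPerimeter:
    def test_axis_aligned_square_chain_identity(self):
        ch = mm.trace_boundary(square_mask(20))
        assert mm.perimeter_chain(ch) == pytest.approx(4 * 19)

    def test_disk_perimeter_conventions(self):
        """Plain chain code overestimates a smooth circle by its known
        ~5% bias; the corner-corrected estimator is within 3% of 2*pi*r."""
        disk = rasterize_disk(50)
        ch = mm.trace_boundary(disk)
        true = 2 * math.pi * 50
        plain = mm.perimeter_chain(ch)
        corrected = mm.perimeter_chain(ch, convention="corner_corrected")
        assert 1.03 < plain / true < 1.07
        assert abs(corrected / true - 1) < 0.03

    def test_diamond_all_diagonal_steps(self):
        yy, xx = np.mgrid[:41, :41]
        diamond = np.abs(yy - 20) + np.abs(xx - 20) <= 12
        ch = mm.trace_boundary(diamond)
        assert np.all(ch.codes % 2 == 1)
        assert mm.perimeter_chain(ch) == pytest.approx(
            ch.codes.size * math.sqrt(2))

    def test_degenerate_fallbacks(self):
        one = np.zeros((3, 3), bool)
        one[1, 1] = True
        assert mm.perimeter_chain(mm.trace_boundary(one)) == 4.0
        domino = np.zeros((3, 4), bool)
        domino[1, 1:3] = True
        assert mm.perimeter_chain(mm.trace_boundary(domino)) == 6.0
        diag = np.zeros((4, 4), bool)
        diag[1, 1] = diag[2, 2] = True
        assert mm.perimeter_chain(mm.trace_boundary(diag)) == 8.0


class TestCircularity:
    @pytest.mark.parametrize("area,perim,expected", [
        (math.pi * 10**2, 2 * math.pi * 10, 1.0),        # continuum disk
        (20.0**2, 4 * 20.0, math.pi / 4),                # continuum square
        (100.0, 10.0, 1.0),                              # 4*pi*A/P^2 > 1: cap
    ])
    def test_closed_forms(self, area, perim, expected):
        assert mm.circularity(area, perim) == pytest.approx(expected)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            mm.circularity(0.0, 10.0)


class TestSolidity:
    def test_plus_sign_five_sevenths(self):
        plus = np.zeros((5, 5), bool)
        plus[2, 1:4] = True
        plus[1:4, 2] = True
        _, sol = mm.convex_solidity(plus)
        assert sol == pytest.approx(5 / 7)

    def test_rectangle_is_convex(self):
        rect = np.zeros((30, 40), bool)
        rect[5:25, 5:35] = True
        _, sol = mm.convex_solidity(rect)
        assert sol >= 0.98

    def test_rotation_90_invariance(self, rng):
        blob = ndimage.binary_dilation(rng.random((20, 20)) < 0.05,
                                       iterations=4)
        lab, _ = ndimage.label(blob)
        comp = lab == 1
        _, a = mm.convex_solidity(comp)
        _, b = mm.convex_solidity(np.rot90(comp))
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounded_by_one(self, rng):
        for _ in range(20):
            blob = ndimage.binary_dilation(rng.random((16, 16)) < 0.08,
                                           iterations=2)
            lab, n = ndimage.label(blob)
            for k in range(1, n + 1):
                _, sol = mm.convex_solidity(lab == k)
                assert 0.0 < sol <= 1.0


class TestEllipseFit:
    def test_axis_aligned_ellipse(self):
        mask = rasterize_ellipse(40, 20)
        major, minor, angle = mm.fit_ellipse_moments(mask)
        assert major == pytest.approx(80, rel=0.02)
        assert minor == pytest.approx(40, rel=0.02)
        assert min(angle, 180 - angle) < 2.0

    def test_disk_isotropy(self):
        mask = rasterize_disk(30)
        major, minor, _ = mm.fit_ellipse_moments(mask)
        assert major == pytest.approx(minor, rel=0.01)

    def test_rotated_30_degrees(self):
        mask = rasterize_ellipse(40, 20, angle_deg=30)
        major, minor, angle = mm.fit_ellipse_moments(mask)
        assert abs(angle - 30) < 2.0
        assert major == pytest.approx(80, rel=0.02)

    def test_area_preserving_scaling(self):
        mask = rasterize_ellipse(35, 18)
        major, minor, _ = mm.fit_ellipse_moments(mask)
        assert math.pi * (major / 2) * (minor / 2) == pytest.approx(
            mask.sum(), rel=1e-9)

    def test_collinear_degenerate(self):
        line = np.zeros((5, 9), bool)
        line[2, 1:8] = True
        major, minor, angle = mm.fit_ellipse_moments(line)
        assert minor == 0.0 and abs(angle % 180) < 1e-9


class TestFeret:
    def test_rectangle_closed_form(self):
        rect = np.zeros((20, 40), bool)
        rect[5:15, 5:35]: bool
        rect[5:15, 5:35] = True
        hull = mm.pixel_corner_hull(rect)
        fmax, fmin = mm.feret_diameters(hull)
        assert fmax == pytest.approx(math.hypot(30, 10))
        assert fmin == pytest.approx(10.0)

    def test_equilateral_triangle_closed_form(self):
        s = 10.0
        tri = np.array([[0, 0], [s, 0], [s / 2, s * math.sqrt(3) / 2]])
        fmax, fmin = mm.feret_diameters(tri)
        assert fmax == pytest.approx(s)
        assert fmin == pytest.approx(s * math.sqrt(3) / 2)

    def test_calipers_match_angle_sweep_oracle(self, rng):
        """Rotating calipers equals a brute-force quarter-degree
        projection sweep (the sweep can only overestimate the min
        width, linearly in the angular step at a width-function kink)."""
        thetas = np.deg2rad(np.arange(0, 720) / 4.0)
        dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])
        for _ in range(100):
            pts = rng.random((12, 2)) * 50
            from scipy.spatial import ConvexHull
            hull = pts[ConvexHull(pts).vertices]
            fmax, fmin = mm.feret_diameters(hull)
            proj = hull @ dirs.T
            widths = proj.max(0) - proj.min(0)
            assert fmax == pytest.approx(widths.max(), rel=0.005)
            assert fmin <= widths.min() + 1e-9
            assert fmin == pytest.approx(widths.min(), rel=0.005)


class TestInvariances:
    def test_translation_invariance(self, rng):
        mask = rasterize_ellipse(20, 12, angle_deg=15, size=80)
        f1 = mm.measure_clusters(mask.astype(int))[0]
        f2 = mm.measure_clusters(np.roll(mask, (7, 11), (0, 1)).astype(int))[0]
        for k in mm.DESCRIPTOR_NAMES:
            assert getattr(f1, k) == pytest.approx(getattr(f2, k), abs=1e-9)

    def test_rotation_invariance_within_discretization(self):
        m0 = rasterize_ellipse(30, 16, angle_deg=0, size=90)
        m1 = rasterize_ellipse(30, 16, angle_deg=37, size=90)
        f0 = mm.measure_clusters(m0.astype(int))[0]
        f1 = mm.measure_clusters(m1.astype(int))[0]
        assert f1.area == pytest.approx(f0.area, rel=0.02)
        assert f1.feret_max == pytest.approx(f0.feret_max, rel=0.02)
        assert abs(f1.circularity - f0.circularity) < 0.02
        assert abs(f1.solidity - f0.solidity) < 0.02

    def test_scaling_relations(self):
        small = rasterize_ellipse(40, 24, size=120)
        big = rasterize_ellipse(80, 48, size=200)
        fs = mm.measure_clusters(small.astype(int))[0]
        fb = mm.measure_clusters(big.astype(int))[0]
        assert fb.area == pytest.approx(4 * fs.area, rel=0.03)
        assert fb.perimeter == pytest.approx(2 * fs.perimeter, rel=0.03)
        assert fb.feret_max == pytest.approx(2 * fs.feret_max, rel=0.03)
        assert fb.fit_ellipse_major == pytest.approx(
            2 * fs.fit_ellipse_major, rel=0.03)
        assert abs(fb.circularity - fs.circularity) < 0.02
        assert abs(fb.solidity - fs.solidity) < 0.02
        # box counting is scale-covariant: doubling the mask and the box
        # sizes together leaves the log-log slope unchanged
        sizes = (2, 3, 4, 6, 8, 12, 16)
        doubled = tuple(2 * s for s in sizes)
        assert abs(mm.boxcount_fd(big, sizes=doubled)
                   - mm.boxcount_fd(small, sizes=sizes)) < 0.05


class TestAggregation:
    def _cluster(self, **kw):
        base = dict(area=100.0, perimeter=40.0, circularity=0.5,
                    fit_ellipse_major=20.0, fit_ellipse_minor=10.0,
                    angle=10.0, solidity=0.9, feret_max=22.0, feret_min=9.0)
        base.update(kw)
        return mm.ClusterFeatures(**base)

    def test_single_cluster_field_is_identity(self):
        c = self._cluster()
        ff = mm.summarize_field([c], fractal_dimension=1.3)
        for k in mm.DESCRIPTOR_NAMES:
            assert ff.means[k] == pytest.approx(getattr(c, k))
        assert ff.cluster_count == 1

    def test_two_cluster_mean(self):
        ff = mm.summarize_field(
            [self._cluster(circularity=0.4), self._cluster(circularity=0.8)],
            fractal_dimension=1.3)
        assert ff.means["circularity"] == pytest.approx(0.6)

    def test_empty_field_flagged(self):
        ff = mm.summarize_field([], fractal_dimension=float("nan"))
        assert not ff.defined and ff.cluster_count == 0
        assert math.isnan(ff.means["circularity"])

    def test_axial_angle_mean_wraps(self):
        ff = mm.summarize_field(
            [self._cluster(angle=178.0), self._cluster(angle=2.0)],
            fractal_dimension=1.0)
        assert ff.means["angle"] == pytest.approx(0.0, abs=1e-6) or \
            ff.means["angle"] == pytest.approx(180.0, abs=1e-6)

    def test_specimen_mean_is_fixed_point_on_constant_fields(self):
        ff = mm.summarize_field([self._cluster()], fractal_dimension=1.3)
        spec = mm.summarize_specimen([ff] * 5)
        for k in mm.DESCRIPTOR_NAMES:
            assert spec.means[k] == pytest.approx(ff.means[k])
        assert spec.fractal_dimension == pytest.approx(1.3)
        assert spec.complete and spec.n_fields_used == 5

    def test_specimen_fd_mean(self):
        fields = [mm.summarize_field([self._cluster()], fd)
                  for fd in (1.2, 1.3, 1.4, 1.3, 1.3)]
        spec = mm.summarize_specimen(fields)
        assert spec.fractal_dimension == pytest.approx(1.30)

    def test_empty_field_among_five(self):
        """Descriptor means use the 4 defined fields; fd uses all fields
        where any foreground exists (here the empty field has none)."""
        good = [mm.summarize_field([self._cluster(circularity=c)], 1.3)
                for c in (0.4, 0.5, 0.6, 0.7)]
        empty = mm.summarize_field([], fractal_dimension=float("nan"))
        spec = mm.summarize_specimen(good + [empty])
        assert spec.means["circularity"] == pytest.approx(0.55)
        assert spec.fractal_dimension == pytest.approx(1.3)
        assert spec.n_fields_used == 4 and not spec.complete

    def test_all_fields_empty_raises(self):
        empty = mm.summarize_field([], fractal_dimension=float("nan"))
        with pytest.raises(ValueError):
            mm.summarize_specimen([empty, empty])
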