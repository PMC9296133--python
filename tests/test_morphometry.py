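import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nedyn import morphometry as mm
from nedyn import synth
from nedyn.errors import GeometryError, InputError, SegmentationError

SPHERE_VOL_R4 = (4.0 / 3.0) * math.pi * 64.0  # 268.0826 um^3


def _regular_polygon(n, r, center=(0.0, 0.0)):
    th = 2 * math.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


class TestPolygonArea:
    def test_unit_square_exact(self):
        assert mm.polygon_area([[0, 0], [1, 0], [1, 1], [0, 1]]) == 1.0

    def test_orientation_invariance(self):
        assert mm.polygon_area([[0, 1], [1, 1], [1, 0], [0, 0]]) == 1.0

    def test_inscribed_256gon_closed_form(self):
        n, r = 256, 4.0
        area = mm.polygon_area(_regular_polygon(n, r))
        expected = 0.5 * n * r * r * math.sin(2 * math.pi / n)
        assert area == pytest.approx(expected, rel=1e-9)

    def test_self_intersection_is_geometry_error(self):
        with pytest.raises(GeometryError):
            mm.polygon_area([[0, 0], [1, 1], [1, 0], [0, 1]])  # bowtie

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0),
           st.integers(min_value=3, max_value=64))
    def test_scaling_property(self, s, n):
        verts = _regular_polygon(n, 1.0)
        base = mm.polygon_area(verts)
        assert mm.polygon_area(verts * s) == pytest.approx(base * s * s,
                                                           rel=1e-9)


class TestVolumes:
    def test_single_square_slice(self):
        stack = mm.ContourStack(
            slices=[(0, np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))],
            z_step_um=0.1625)
        assert mm.contour_volume(stack) == pytest.approx(0.1625)

    def test_sphere_volume_within_1pct(self):
        stack = synth.gen_sphere_contours(4.0, 0.1625, 256, 0.0)
        assert mm.contour_volume(stack) == pytest.approx(SPHERE_VOL_R4,
                                                         rel=0.01)
        assert mm.theoretical_volume(stack) == pytest.approx(SPHERE_VOL_R4,
                                                             rel=0.01)

    def test_theoretical_volume_from_widest_slice(self):
        sq = math.sqrt(math.pi)  # square of area pi -> r = 1
        stack = mm.ContourStack(
            slices=[(0, np.array([[0, 0], [sq, 0], [sq, sq], [0, sq]]))])
        assert mm.theoretical_volume(stack) == pytest.approx(4 * math.pi / 3)

    def test_widest_of_two_slices(self):
        # squares of areas pi and 4*pi -> r_max = 2 -> V = 32*pi/3
        a, b = math.sqrt(math.pi), math.sqrt(4 * math.pi)
        stack = mm.ContourStack(slices=[
            (0, np.array([[0, 0], [a, 0], [a, a], [0, a]])),
            (1, np.array([[0, 0], [b, 0], [b, b], [0, b]])),
        ])
        assert mm.theoretical_volume(stack) == pytest.approx(32 * math.pi / 3)

    def test_empty_stack_is_geometry_error(self):
        with pytest.raises(GeometryError):
            mm.ContourStack(slices=[])

    def test_bad_slice_named_in_error(self):
        stack = mm.ContourStack(slices=[
            (0, _regular_polygon(16, 1.0)),
            (3, np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)),
        ])
        with pytest.raises(GeometryError, match="slice 3"):
            mm.contour_volume(stack)

    def test_coordinate_scaling_scales_volume_cubically(self):
        stack = synth.gen_sphere_contours(2.0, 0.25, 64, 0.0)
        v = mm.contour_volume(stack)
        scaled = mm.ContourStack(
            slices=[(z, verts * 3.0) for z, verts in stack.slices],
            z_step_um=stack.z_step_um * 3.0)
        assert mm.contour_volume(scaled) == pytest.approx(27.0 * v, rel=1e-12)


class TestSphericity:
    def test_ideal_sphere_passes(self):
        stack = synth.gen_sphere_contours(4.0, 0.1625, 256, 0.0)
        res = mm.sphericity_check(stack)
        assert res.deviation < 0.02
        assert res.within_10pct

    def test_prolate_ellipsoid_fails(self):
        # semi-axes (4, 4, 8): V = 4/3*pi*4*4*8 ~ 536; widest slice gives
        # a sphere of ~268 -> deviation ~ 1.0
        h = 0.25
        slices = []
        for k in range(-31, 32):
            z = k * h
            rho = 4.0 * math.sqrt(max(0.0, 1.0 - (z / 8.0) ** 2))
            slices.append((k, _regular_polygon(128, rho)))
        stack = mm.ContourStack(slices=slices, z_step_um=h)
        res = mm.sphericity_check(stack)
        assert res.integrated_um3 == pytest.approx(536.165, rel=0.05)
        assert res.theoretical_um3 == pytest.approx(268.08, rel=0.02)
        assert res.deviation > 0.5
        assert not res.within_10pct

    def test_identical_volumes_deviation_zero(self):
        stack = mm.ContourStack(slices=[(0, _regular_polygon(64, 1.0))],
                                z_step_um=4.0 / 3.0)
        # one slice: integrated = A*h; pick h so V_int == V_theo
        a = mm.polygon_area(_regular_polygon(64, 1.0))
        r = math.sqrt(a / math.pi)
        stack.z_step_um = (4.0 / 3.0) * r ** 3 * math.pi / a
        res = mm.sphericity_check(stack)
        assert res.deviation == pytest.approx(0.0, abs=1e-12)

    def test_refinement_converges_monotonically(self):
        errors = []
        for i, n in enumerate([16, 32, 64, 128]):
            stack = synth.gen_sphere_contours(4.0, 0.65 / 2 ** i, n, 0.0)
            errors.append(abs(mm.contour_volume(stack) - SPHERE_VOL_R4))
        assert all(b < a for a, b in zip(errors, errors[1:]))


class TestDiameter:
    def test_rasterized_disk(self):
        yy, xx = np.ogrid[:128, :128]
        frame = np.where((xx - 64) ** 2 + (yy - 64) ** 2 <= 20 ** 2,
                         200.0, 50.0)
        geo = mm.measure_diameter(frame, pixel_size_um=0.1)
        assert geo.diameter_um == pytest.approx(4.0, abs=0.05)
        assert geo.volume_um3 == pytest.approx(
            (4 / 3) * math.pi * (geo.diameter_um / 2) ** 3, rel=1e-12)
        assert geo.surface_area_um2 == pytest.approx(
            4 * math.pi * (geo.diameter_um / 2) ** 2, rel=1e-12)

    def test_eight_micron_pronucleus_volume(self):
        geo = mm.NucleusGeometry.from_diameter(8.0)
        assert geo.volume_um3 == pytest.approx(268.08, abs=0.01)

    def test_zero_diameter_degenerate(self):
        assert mm.NucleusGeometry.from_diameter(0.0).volume_um3 == 0.0

    def test_constant_frame_is_segmentation_error(self):
        with pytest.raises(SegmentationError):
            mm.measure_diameter(np.zeros((32, 32)), 0.1)


class TestGrowthRate:
    def test_exact_line(self):
        res = mm.growth_rate([(0, 10.0), (10, 20.0), (20, 30.0)])
        assert res.rate_um3_per_s == pytest.approx(1.0)
        assert res.intercept_um3 == pytest.approx(10.0)

    def test_constant_volume(self):
        res = mm.growth_rate([(0, 5.0), (10, 5.0), (20, 5.0)])
        assert res.rate_um3_per_s == pytest.approx(0.0)

    def test_noisy_slope_within_sampling_error(self):
        rng = np.random.default_rng(6)
        t = np.arange(20.0)
        v = 2.0 + 0.5 * t + rng.normal(0, 1.0, 20)
        res = mm.growth_rate(list(zip(t, v)))
        # closed-form OLS slope variance: sigma^2 / sum((t - tbar)^2)
        se = 1.0 / math.sqrt(((t - t.mean()) ** 2).sum())
        assert abs(res.rate_um3_per_s - 0.5) < 2 * se

    def test_too_few_points(self):
        with pytest.raises(InputError):
            mm.growth_rate([(0, 1.0), (1, 2.0)])
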