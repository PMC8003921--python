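"""Line analysis: lattice geometry, Bresenham properties, shell metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreshell.phantom import render_geometry_phantom
from coreshell.radial_lines import (
    RadialLine,
    aggregate_lines,
    angular_trend,
    bresenham_3d,
    concentric_layer_ratios,
    direction_from_angles,
    fibonacci_directions,
    find_core_center,
    line_metrics,
    sample_surface_points,
    spherical_angles,
    trace_lines,
)
from coreshell.recovery import mask_centroid
from coreshell.stacks import BinaryMask3D

from conftest import make_ball_mask


class TestCoreCenter:
    def test_symmetric_uniform_core_gives_geometric_center(self):
        ball = make_ball_mask((33, 33, 33), (1, 1, 1), (16, 16, 16), 8.0)
        empty = BinaryMask3D(np.zeros(ball.shape, bool), (1, 1, 1))
        center = find_core_center(np.ones(ball.shape), ball, empty)
        np.testing.assert_allclose(center, (16, 16, 16), atol=1e-9)

    def test_two_voxel_weighted_mean(self):
        mask = np.zeros((4, 1, 1), bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        intens = np.zeros((4, 1, 1))
        intens[0, 0, 0], intens[1, 0, 0] = 1.0, 3.0
        m = BinaryMask3D(mask, (2.0, 2.0, 2.0))
        empty = BinaryMask3D(np.zeros_like(mask), (2.0, 2.0, 2.0))
        center = find_core_center(intens, m, empty)
        assert center[0] == pytest.approx(0.75 * 2.0)  # ¼ : ¾ split

    def test_fallback_when_difference_empty(self):
        ball = make_ball_mask((17, 17, 17), (1, 1, 1), (8, 8, 8), 5.0)
        with pytest.warns(UserWarning, match="fall"):
            center = find_core_center(np.ones(ball.shape), ball, ball)
        np.testing.assert_allclose(center, (8, 8, 8), atol=1e-9)

    def test_phantom_center_recovered_within_one_voxel(self, small_full_spec):
        whole, shell, core = render_geometry_phantom(small_full_spec)
        dapi = whole
        center = find_core_center(np.ones(whole.shape), dapi, shell)
        np.testing.assert_allclose(
            center, small_full_spec.center, atol=max(small_full_spec.spacing)
        )


class TestConcentricLayers:
    def test_farred_everywhere_gives_unit_ratios(self):
        ball = make_ball_mask((33, 33, 33), (1, 1, 1), (16, 16, 16), 12.0)
        full = BinaryMask3D(np.ones(ball.shape, bool), (1, 1, 1))
        prof = concentric_layer_ratios(ball, full, np.array([16.0, 16.0, 16.0]), 5.0)
        assert (prof["farred_fraction"] == 1.0).all()
        assert prof["n_voxels"].sum() == ball.data.sum()

    def test_core_layers_empty_shell_layers_high(self, small_full_spec):
        whole, shell, _ = render_geometry_phantom(small_full_spec)
        center = np.asarray(small_full_spec.center)
        prof = concentric_layer_ratios(whole, shell, center, 5.0)
        inner = prof[prof["outer_um"] <= 10.0]["farred_fraction"]
        outer = prof[(prof["inner_um"] >= 25.0) & (prof["outer_um"] <= 30.0)]
        assert (inner == 0.0).all()
        assert (outer["farred_fraction"] > 0.9).all()

    def test_single_layer_mask(self):
        ball = make_ball_mask((17, 17, 17), (1, 1, 1), (8, 8, 8), 3.0)
        prof = concentric_layer_ratios(
            ball, ball, np.array([8.0, 8.0, 8.0]), layer_width=50.0
        )
        assert len(prof) == 1
        assert prof.loc[0, "n_voxels"] == ball.data.sum()

    def test_nonpositive_width_rejected(self):
        ball = make_ball_mask((9, 9, 9), (1, 1, 1), (4, 4, 4), 2.0)
        with pytest.raises(ValueError):
            concentric_layer_ratios(ball, ball, np.array([4.0, 4.0, 4.0]), 0.0)


class TestFibonacciLattice:
    def test_two_points_are_antipodal(self):
        d = fibonacci_directions(2)
        np.testing.assert_allclose(d[0], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(d[1] + d[0], 0, atol=1e-12)

    def test_unit_norm_and_deterministic(self):
        a = fibonacci_directions(997)
        b = fibonacci_directions(997)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)

    def test_nearest_neighbor_spacing_varies_less_than_twofold(self):
        d = fibonacci_directions(5000)
        nn = np.empty(5000)
        for lo in range(0, 5000, 500):
            dots = d[lo : lo + 500] @ d.T
            np.fill_diagonal(dots[:, lo : lo + 500], -1.0)
            nn[lo : lo + 500] = np.arccos(np.clip(dots.max(axis=1), -1, 1))
        assert nn.max() / nn.min() < 2.0

    def test_angle_mapping_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            theta = rng.uniform(-math.pi, math.pi)
            phi = rng.uniform(-math.pi / 2, math.pi / 2)
            vec = direction_from_angles(theta, phi)
            t2, p2 = spherical_angles(vec)
            assert p2[0] == pytest.approx(phi, abs=1e-9)
            if abs(abs(phi) - math.pi / 2) > 1e-6:  # azimuth undefined at poles
                assert t2[0] == pytest.approx(theta, abs=1e-6)


class TestSurfaceSampling:
    def test_ball_radii_within_half_voxel_of_analytic(self):
        R = 20.0
        ball = make_ball_mask((96,) * 3, (0.45,) * 3, (21.4,) * 3, R)
        _, surface, r, clamped = sample_surface_points(
            ball, np.array([21.4] * 3), 2000
        )
        assert not clamped.any()
        # oracle: exact ray-sphere intersection is R for every direction.
        # voxel centers never lie outside the ball, a ray exiting through a
        # voxel corner can stop ~a voxel diagonal short, and the mean stays
        # within half a voxel
        assert np.all(r <= R + 1e-9)
        assert np.abs(r - R).max() <= 2 * 0.45
        assert np.abs(r - R).mean() <= 0.225

    def test_center_outside_mask_rejected(self):
        ball = make_ball_mask((32,) * 3, (1,) * 3, (16,) * 3, 6.0)
        with pytest.raises(ValueError, match="center"):
            sample_surface_points(ball, np.array([1.0, 1.0, 1.0]), 10)

    def test_mask_touching_grid_edge_clamps_with_warning(self):
        data = np.ones((16, 16, 16), bool)
        mask = BinaryMask3D(data, (1, 1, 1))
        with pytest.warns(UserWarning, match="clamped"):
            _, _, _, clamped = sample_surface_points(mask, np.array([8.0, 8.0, 8.0]), 64)
        assert clamped.any()


class TestBresenham3D:
    def test_axis_aligned(self):
        path = bresenham_3d((0, 0, 0), (3, 0, 0))
        np.testing.assert_array_equal(path, [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])

    def test_main_diagonal(self):
        path = bresenham_3d((0, 0, 0), (2, 2, 2))
        np.testing.assert_array_equal(path, [[0, 0, 0], [1, 1, 1], [2, 2, 2]])

    def test_degenerate_single_voxel(self):
        np.testing.assert_array_equal(bresenham_3d((5, 5, 5), (5, 5, 5)), [[5, 5, 5]])

    def test_digital_line_properties_over_random_pairs(self):
        """1000 random pairs in 32³: endpoints exact, 26-adjacency, per-axis
        monotonicity, length = max axis delta + 1."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.integers(0, 32, size=3)
            b = rng.integers(0, 32, size=3)
            path = bresenham_3d(a, b)
            np.testing.assert_array_equal(path[0], a)
            np.testing.assert_array_equal(path[-1], b)
            assert len(path) == np.abs(b - a).max() + 1
            steps = np.diff(path, axis=0)
            assert np.abs(steps).max(initial=0) <= 1
            assert (np.abs(steps).sum(axis=1) > 0).all()
            for axis in range(3):
                d = steps[:, axis]
                assert (d >= 0).all() or (d <= 0).all()


class TestLineMetrics:
    def _line_fixture(self, pattern):
        n = len(pattern)
        farred = np.zeros((n, 1, 1), bool)
        for i, ch in enumerate(pattern):
            farred[i, 0, 0] = ch == "P"
        path = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
        return path, BinaryMask3D(farred, (1.0, 1.0, 1.0))

    def test_counting_pattern(self):
        path, mask = self._line_fixture("NNNNNNNPPP")
        thickness, core_r, covered, step = line_metrics(path, mask, r=10.0)
        assert step == 1.0
        assert thickness == pytest.approx(3.0)
        assert core_r == pytest.approx(7.0)
        assert covered

    def test_no_positives(self):
        path, mask = self._line_fixture("NNNNN")
        thickness, core_r, covered, _ = line_metrics(path, mask, r=5.0)
        assert thickness == 0.0
        assert math.isnan(core_r)
        assert not covered

    def test_empty_line_rejected(self):
        _, mask = self._line_fixture("N")
        with pytest.raises(ValueError):
            line_metrics(np.zeros((0, 3), int), mask, r=1.0)


def _fake_line(theta=0.0, phi=0.0, r=10.0, thickness=0.0, covered=False):
    return RadialLine(
        theta=theta, phi=phi, surface_point=np.zeros(3), r=r,
        path=np.zeros((1, 3), int), step=1.0, shell_thickness=thickness,
        core_radius=5.0 if covered else float("nan"), covered=covered,
    )


class TestAggregateAndTrend:
    def test_coverage_percentage_arithmetic(self):
        lines = [_fake_line(covered=True, thickness=20.0)] * 4562
        lines += [_fake_line(covered=False)] * 438
        s = aggregate_lines(lines)
        assert s["coverage_percent"] == pytest.approx(91.24)

    def test_all_covered_and_none_covered(self):
        assert aggregate_lines([_fake_line(covered=True, thickness=5.0)] * 10)[
            "coverage_percent"
        ] == 100.0
        s = aggregate_lines([_fake_line(covered=False)] * 10)
        assert s["coverage_percent"] == 0.0
        assert s["mean_shell_thickness_um"] == 0.0

    def test_uniform_shell_has_flat_trends(self, small_full_spec):
        whole, shell, _ = render_geometry_phantom(small_full_spec)
        center = mask_centroid(whole)
        lines = trace_lines(whole, shell, center, 1500)
        for axis in ("azimuth", "polar"):
            trend = angular_trend(lines, axis)
            means = trend["mean_thickness_um"].dropna()
            assert means.max() - means.min() < 2.0  # µm, sampling tolerance

    def test_cap_phantom_depresses_only_bottom_polar_bins(self, small_cap_spec):
        whole, shell, _ = render_geometry_phantom(small_cap_spec)
        center = mask_centroid(whole)
        lines = trace_lines(whole, shell, center, 2000)
        trend = angular_trend(lines, "polar")
        import math as m

        alpha = m.acos(2 * small_cap_spec.coverage_fraction - 1)
        cap_edge = -(m.pi / 2 - alpha)
        in_cap = trend["bin_right"] <= cap_edge
        above = trend["bin_left"] >= -m.pi / 4
        assert (trend.loc[in_cap, "mean_thickness_um"] < 2.0).all()
        assert (
            trend.loc[above, "mean_thickness_um"]
            > 0.8 * small_cap_spec.shell_thickness
        ).all()

    def test_single_line_single_bin_sd_undefined(self):
        trend = angular_trend([_fake_line(theta=0.1, phi=0.2, thickness=3.0)], "polar")
        populated = trend[trend["n"] > 0]
        assert len(populated) == 1
        assert math.isnan(populated["sd_thickness_um"].iloc[0])

    def test_bin_width_must_divide_range(self):
        with pytest.raises(ValueError):
            angular_trend([_fake_line()], "polar", bin_width=0.7)


class TestTraceLines:
    def test_paths_stay_inside_whole_mask(self, small_full_spec):
        whole, shell, _ = render_geometry_phantom(small_full_spec)
        center = mask_centroid(whole)
        lines = trace_lines(whole, shell, center, 300)
        for ln in lines:
            inside = whole.data[ln.path[:, 0], ln.path[:, 1], ln.path[:, 2]]
            assert inside.all()

    def test_angles_match_surface_points(self, small_full_spec):
        whole, shell, _ = render_geometry_phantom(small_full_spec)
        center = mask_centroid(whole)
        lines = trace_lines(whole, shell, center, 300)
        for ln in lines[:50]:
            offset = ln.surface_point - center
            np.testing.assert_allclose(
                direction_from_angles(ln.theta, ln.phi) * ln.r, offset, atol=1e-6
            )
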