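"""Whole-wing geometry: normalization, orientation, curvature, P and L."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wingmorph as wm
from wingmorph.geometry import (
    curvature_profile,
    fit_circle_kasa,
    internal_vein_length,
    normalize_area,
    normalized_perimeter,
    orient_contour,
    principal_axis_angle,
    resample_contour,
)

TWO_SQRT_PI = 2.0 * np.sqrt(np.pi)


def circle_ring(radius: float = 1.0, n: int = 10_000) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


def ellipse_ring(a: float, b: float, n: int = 4096) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


class TestNormalizeArea:
    def test_square_of_side_two(self):
        v = 2.0 * np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        wing = wm.SegmentedWing(v, np.arange(4), [np.arange(4)])
        norm = normalize_area(wing)
        assert norm.normalized
        assert abs(norm.area - 1.0) < 1e-9
        assert np.allclose(np.ptp(norm.vertices, axis=0), 1.0)

    def test_idempotent(self, circle_wing):
        once = normalize_area(circle_wing)
        twice = normalize_area(once)
        assert np.max(np.abs(twice.vertices - once.vertices)) < 1e-12

    def test_degenerate_area_raises(self):
        v = np.array([[0, 0], [1, 0], [2, 0], [1, 0.000001]])
        wing = wm.SegmentedWing(v, np.arange(4), [np.arange(4)],
                                validate=False)
        stats = internal_vein_length(normalize_area(wing))
        assert np.isfinite(stats.P)     # tiny but valid area still works

    @given(factor=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_dimensionless_stats_scale_invariant(self, factor):
        v = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        wing = wm.SegmentedWing(v, np.arange(4),
                                [np.array([0, 1, 2]), np.array([0, 2, 3])])
        ref = internal_vein_length(wing)
        scaled = internal_vein_length(wing.scaled(factor))
        assert abs(scaled.P - ref.P) <= 1e-9 * max(1, abs(ref.P))
        assert abs(scaled.L - ref.L) <= 1e-9 * max(1, abs(ref.L))
        assert abs(scaled.L_over_P - ref.L_over_P) <= 1e-9


class TestOrientContour:
    def test_ccw_square_becomes_clockwise(self):
        ring = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        oriented = orient_contour(ring)
        from wingmorph.wing_model import ring_area

        assert ring_area(oriented) < 0
        assert np.allclose(oriented[0], [0, 0])     # leftmost, lowest y

    def test_ellipse_midpoint_is_tip(self):
        ring = ellipse_ring(2.0, 1.0)
        oriented = orient_contour(ring)
        assert np.allclose(oriented[0], [-2, 0], atol=1e-2)
        tip = oriented[len(oriented) // 2]
        assert np.allclose(tip, [2, 0], atol=1e-2)

    def test_rotated_ellipse_base_found_on_long_axis(self):
        ring = ellipse_ring(2.0, 1.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        oriented = orient_contour(ring @ rot.T)
        # base should map back to one of the major-axis ends
        base = rot.T @ oriented[0]
        assert abs(abs(base[0]) - 2.0) < 1e-2

    def test_non_simple_contour_rejected(self):
        bow = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(wm.WingModelError):
            orient_contour(bow)

    def test_principal_axis_of_rotated_rectangle(self):
        rect = np.array([[-2, -1], [2, -1], [2, 1], [-2, 1]], dtype=float)
        for theta in (0.0, 0.3, -0.6, 1.2):
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            got = principal_axis_angle(rect @ rot.T)
            expect = np.arctan2(np.sin(theta), np.cos(theta))
            expect = np.arctan(np.tan(expect))      # fold into (-pi/2, pi/2]
            assert abs(np.tan(got) - np.tan(expect)) < 1e-9


class TestCurvature:
    @pytest.mark.parametrize("radius", [0.1, 1.0, 10.0])
    def test_circle_scaled_curvature_is_two_pi(self, radius):
        prof = curvature_profile(circle_ring(radius, 4096), scaled=True)
        assert np.max(np.abs(prof.kappa / (2 * np.pi) - 1.0)) < 1e-3

    def test_straight_segments_have_zero_curvature(self):
        # long thin rectangle: straight stretches dominate
        ring = np.array([[0, 0], [10, 0], [10, 1], [0, 1]], dtype=float)
        prof = curvature_profile(ring, window=0.01)
        # samples well inside the long sides see collinear triples
        assert (prof.kappa == 0).sum() > len(prof.kappa) / 2

    def test_ellipse_extrema_match_closed_form(self):
        # kappa_max = a/b^2 at the major-axis ends, kappa_min = b/a^2
        ring = ellipse_ring(2.0, 1.0, 16384)
        prof = curvature_profile(ring, window=0.005, n_samples=2000)
        assert abs(prof.kappa.max() - 2.0) / 2.0 < 0.01
        assert abs(prof.kappa.min() - 0.25) / 0.25 < 0.01

    def test_window_bias_shrinks_quadratically(self):
        ring = ellipse_ring(2.0, 1.0, 16384)
        errs = [abs(curvature_profile(ring, window=w, n_samples=2000).kappa.max() - 2) / 2
                for w in (0.02, 0.01)]
        assert 3.0 < errs[0] / errs[1] < 5.0

    def test_mirror_symmetry(self):
        ring = ellipse_ring(2.0, 1.0)
        prof = curvature_profile(orient_contour(ring), window=0.02)
        flipped = prof.kappa[::-1]
        # kappa(s) == kappa(1 - s) up to one-sample shift
        assert np.allclose(prof.kappa[1:], flipped[:-1], atol=5e-3)

    def test_kasa_fit_exact_on_circle_points(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cx, cy, r = rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(0.1, 4)
            t = rng.uniform(0, 2 * np.pi, 3)
            pts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
            fx, fy, fr = fit_circle_kasa(pts)
            assert abs(fr - r) < 1e-9 * max(1, r)

    def test_collinear_points_give_zero(self):
        prof = curvature_profile(
            np.array([[0, 0], [4, 0], [4, 4e-9], [0, 4e-9]]), window=0.1)
        assert np.all(prof.kappa[np.isfinite(prof.kappa)] >= 0)

    def test_invalid_window_rejected(self):
        with pytest.raises(wm.WingModelError):
            curvature_profile(circle_ring(1, 100), window=0.5)

    def test_resample_preserves_perimeter(self):
        ring = ellipse_ring(3.0, 1.0, 500)
        from wingmorph.wing_model import ring_perimeter

        fine = resample_contour(ring, 5000)
        assert abs(ring_perimeter(fine) - ring_perimeter(ring)) < 1e-3


class TestNormalizedPerimeter:
    def test_unit_square_closed_form(self):
        ring = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert abs(normalized_perimeter(ring) - (4 - TWO_SQRT_PI)) < 1e-12

    @pytest.mark.parametrize("scale", [1.0, 0.01, 250.0])
    def test_four_to_one_rectangle_any_scale(self, scale):
        ring = scale * np.array([[0, 0], [4, 0], [4, 1], [0, 1]], dtype=float)
        assert abs(normalized_perimeter(ring) - (5 - TWO_SQRT_PI)) < 1e-9

    def test_fine_circle_is_zero(self):
        assert abs(normalized_perimeter(circle_ring())) < 1e-3

    def test_isoperimetric_monotonicity_in_elongation(self):
        values = [normalized_perimeter(ellipse_ring(a, 1.0 / a))
                  for a in (1.0, 1.3, 1.8, 2.5, 4.0)]
        assert all(v >= -1e-9 for v in values)
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_degenerate_boundary_rejected(self):
        with pytest.raises(wm.WingModelError):
            normalized_perimeter(np.array([[0, 0], [1, 0], [2, 0]]))


class TestInternalVeinLength:
    def test_square_with_diagonal_closed_form(self, square_diag_wing):
        stats = internal_vein_length(square_diag_wing)
        assert abs(stats.L - np.sqrt(2)) < 1e-9
        assert abs(stats.L_over_P - np.sqrt(2) / 4) < 1e-9
        assert abs(stats.P - (4 - TWO_SQRT_PI)) < 1e-9

    def test_circular_wing_sits_at_origin(self, circle_wing):
        stats = internal_vein_length(circle_wing)
        assert abs(stats.P) < 1e-3
        assert abs(stats.L) < 1e-6

    def test_matches_shared_edge_oracle(self, battery_wings):
        spec, wing = battery_wings[4]       # 50-domain circle
        wing = normalize_area(wing)
        stats = internal_vein_length(wing)
        # oracle: sum lengths of segments used by exactly two domain rings
        count: dict[tuple[int, int], int] = {}
        for ring in wing.domain_rings:
            for u, v in zip(ring, np.roll(ring, -1)):
                key = (min(u, v), max(u, v))
                count[key] = count.get(key, 0) + 1
        shared = sum(
            np.hypot(*(wing.vertices[a] - wing.vertices[b]))
            for (a, b), c in count.items() if c == 2)
        assert abs(stats.L - shared) < 1e-6

    def test_missing_graph_rejected(self, circle_wing):
        circle_wing.edges = []
        with pytest.raises(wm.WingModelError):
            internal_vein_length(circle_wing)
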