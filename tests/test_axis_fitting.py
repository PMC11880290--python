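import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from drfparams.axis_fitting import (
    AxisFitConfig,
    AxisLine,
    axis_loss,
    choose_frame,
    fit_axis,
    reference_axis,
    sample_interior_points,
    smoothed_distance,
)
from drfparams.contour_extraction import extract_part_contour
from drfparams.mask_io import AP_LABELS, LabelMask, View

from ._oracles import grid_axis_oracle
from .conftest import square_contour


class TestSampleInteriorPoints:
    def test_all_points_inside(self):
        import shapely

        c = square_contour(side=40.0, origin=(5.0, 5.0))
        pts = sample_interior_points(c, AxisFitConfig(n_points=200, seed=1))
        poly = shapely.Polygon(c.vertices)
        assert len(pts) == 200
        assert shapely.contains_xy(poly, pts[:, 0], pts[:, 1]).all()

    def test_same_seed_identical(self):
        c = square_contour(side=40.0)
        cfg = AxisFitConfig(n_points=50, seed=9)
        np.testing.assert_array_equal(sample_interior_points(c, cfg),
                                      sample_interior_points(c, cfg))

    def test_rectangle_empirical_centroid(self):
        c = square_contour(side=60.0, origin=(10.0, 20.0))
        pts = sample_interior_points(c, AxisFitConfig(n_points=10000, seed=2))
        np.testing.assert_allclose(pts.mean(axis=0), [40.0, 50.0], atol=60 * 0.02)

    def test_tiny_contour_rejected(self):
        c = square_contour(side=5.0)
        with pytest.raises(ValueError, match="too small"):
            sample_interior_points(c, AxisFitConfig(n_points=10))


class TestSmoothedDistance:
    def test_zero_at_zero(self):
        assert smoothed_distance(0.0) == 0.0

    def test_hand_value_at_sqrt2(self):
        assert smoothed_distance(math.sqrt(2)) == pytest.approx(2 * (math.sqrt(2) - 1))

    @pytest.mark.parametrize("d", [0.5, 1.0, 3.0, 10.0])
    def test_even(self, d):
        assert smoothed_distance(-d) == pytest.approx(smoothed_distance(d), rel=1e-12)

    def test_quadratic_near_zero(self):
        d = 1e-4
        assert smoothed_distance(d) / d ** 2 == pytest.approx(0.5, abs=1e-6)

    def test_linear_at_infinity(self):
        # exact deviation from the sqrt(2) asymptote is 2/d - O(1/d^2),
        # so 1e-6 closeness needs d = 1e7 (at d = 1e6 it is 2e-6)
        d = 1e7
        assert smoothed_distance(d) / d == pytest.approx(math.sqrt(2), abs=1e-6)
        d = 1e6
        assert smoothed_distance(d) / d == pytest.approx(math.sqrt(2) - 2 / d, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_strictly_increasing_in_magnitude(self, d, delta):
        assert smoothed_distance(d + delta) > smoothed_distance(d)


class TestAxisLoss:
    def test_collinear_points_zero(self):
        x = np.linspace(0, 10, 25)
        pts = np.column_stack([x, 2 * x + 1])
        assert axis_loss(pts, 2.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_residual_one(self):
        pts = np.array([[0.0, 1.0]])
        assert axis_loss(pts, 0.0, 0.0) == pytest.approx(2 * (math.sqrt(1.5) - 1))

    def test_additive_over_subsets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 2))
        total = axis_loss(pts, 0.3, -0.2)
        assert total == pytest.approx(axis_loss(pts[:15], 0.3, -0.2)
                                      + axis_loss(pts[15:], 0.3, -0.2))


class TestFitAxis:
    def test_exact_recovery_on_collinear_points(self):
        x = np.linspace(-5, 5, 40)
        pts = np.column_stack([x, 0.4 * x + 3.0])
        axis = fit_axis(pts, AxisFitConfig(tol=1e-14, max_iter=20000))
        assert axis.frame == "xy"
        assert axis.m == pytest.approx(0.4, abs=1e-6)
        assert axis.b == pytest.approx(3.0, abs=1e-6)
        assert axis.loss < 1e-10

    def test_jittered_line_beats_grid_oracle(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 100, 60)
        pts = np.column_stack([x, 0.1 * x + 5 + rng.uniform(-1, 1, len(x))])
        axis = fit_axis(pts, AxisFitConfig())
        assert abs(axis.m - 0.1) <= 0.02
        oracle_loss, _, _ = grid_axis_oracle(pts, axis.frame)
        assert axis.loss <= oracle_loss * (1 + 1e-3) + 1e-9

    def test_vertical_cloud_uses_swapped_frame(self):
        y = np.linspace(0, 200, 80)
        pts = np.column_stack([50 + 0.01 * y, y])
        axis = fit_axis(pts, AxisFitConfig())
        assert axis.frame == "swapped"
        assert axis.theta_deg == pytest.approx(90.0, abs=1.0)

    @pytest.mark.parametrize("phi", [-10.0, -5.0, 5.0, 10.0])
    def test_rotation_equivariance(self, phi):
        rng = np.random.default_rng(3)
        y = np.linspace(0, 150, 60)
        pts = np.column_stack([30 + rng.uniform(-4, 4, len(y)), y])
        base = fit_axis(pts, AxisFitConfig()).theta_deg
        from drfparams._geometry import rotate_points

        rotated = rotate_points(pts, phi, center=pts.mean(axis=0))
        theta = fit_axis(rotated, AxisFitConfig()).theta_deg
        diff = (theta - base - phi + 90) % 180 - 90
        assert abs(diff) <= 0.5

    def test_doubling_points_is_stable(self, default_phantom):
        ap, _, _ = default_phantom
        contour = extract_part_contour(ap, "ulna")
        t1 = fit_axis(sample_interior_points(contour, AxisFitConfig(n_points=500, seed=1)),
                      AxisFitConfig()).theta_deg
        t2 = fit_axis(sample_interior_points(contour, AxisFitConfig(n_points=1000, seed=99)),
                      AxisFitConfig()).theta_deg
        assert abs(t1 - t2) <= 0.5

    def test_fixed_step_descent_also_converges(self):
        x = np.linspace(-5, 5, 40)
        pts = np.column_stack([x, 0.4 * x + 3.0])
        axis = fit_axis(pts, AxisFitConfig(alpha=1e-4, max_iter=20000,
                                           backtracking=False))
        assert axis.m == pytest.approx(0.4, abs=1e-3)

    def test_non_convergence_flagged(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 2)) * 40
        with pytest.warns(RuntimeWarning, match="did not converge"):
            axis = fit_axis(pts, AxisFitConfig(max_iter=2, tol=0.0))
        assert not axis.converged

    def test_coincident_points_rejected(self):
        pts = np.ones((20, 2))
        with pytest.raises(ValueError, match="coincident"):
            fit_axis(pts, AxisFitConfig())


class TestOracleEquivalence:
    """Seeded clouds: descent must match the exhaustive grid minimum."""

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_at_most_grid_minimum(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:   # collinear
            x = np.linspace(0, 80, 50)
            pts = np.column_stack([x, 0.25 * x + 7])
        elif kind == 1:  # jittered
            x = np.linspace(0, 80, 50)
            pts = np.column_stack([x, -0.15 * x + 40 + rng.uniform(-2, 2, len(x))])
        else:           # vertical shaft blob
            y = np.linspace(0, 120, 50)
            pts = np.column_stack([60 + rng.uniform(-6, 6, len(y)), y])
        axis = fit_axis(pts, AxisFitConfig())
        oracle_loss, _, _ = grid_axis_oracle(pts, axis.frame)
        assert axis.loss <= oracle_loss * (1 + 1e-3) + 1e-9


class TestReferenceAxis:
    def test_ap_vertical_ulna(self, default_phantom):
        ap, _, truth = default_phantom
        axis = reference_axis(ap, AxisFitConfig(seed=4))
        assert truth.ap_axis_theta - 1.0 <= axis.theta_deg <= truth.ap_axis_theta + 1.0

    def test_lat_proximal_radius(self):
        from drfparams.phantom import PhantomSpec, generate_phantom

        _, lat, truth = generate_phantom(PhantomSpec(shaft_angle_deg=85.0, seed=6))
        axis = reference_axis(lat, AxisFitConfig(seed=4))
        assert abs(axis.theta_deg - 85.0) <= 1.0

    def test_missing_ulna_rejected(self, default_phantom):
        ap, _, _ = default_phantom
        stripped = ap.pixels.copy()
        stripped[stripped == AP_LABELS["ulna"]] = 0
        mask = LabelMask(stripped, View.AP, dict(AP_LABELS))
        with pytest.raises(ValueError, match="empty part"):
            reference_axis(mask)


class TestAxisLine:
    def test_from_theta_round_trip(self):
        for theta in (0.5, 30.0, 60.0, 90.0, 120.0, 179.0):
            axis = AxisLine.from_theta(theta, (100.0, 200.0))
            assert axis.theta_deg == pytest.approx(theta, abs=1e-9)
            d = axis.direction_distal()
            assert d[1] <= 0 or (d[1] == 0 and d[0] > 0)

    def test_direction_and_perpendicular_orthogonal(self):
        axis = AxisLine.from_theta(75.0, (0.0, 0.0))
        assert axis.direction_distal() @ axis.perpendicular_radial() == pytest.approx(0.0)

    def test_vertical_axis_perpendicular_points_radial(self):
        axis = AxisLine.from_theta(90.0, (10.0, 10.0))
        np.testing.assert_allclose(axis.direction_distal(), [0.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(axis.perpendicular_radial(), [1.0, 0.0], atol=1e-12)

    def test_choose_frame(self):
        tall = np.column_stack([np.zeros(20), np.linspace(0, 50, 20)])
        wide = tall[:, ::-1]
        assert choose_frame(tall) == "swapped"
        assert choose_frame(wide) == "xy"
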