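"""Forward elastica model: drag law, equilibrium shapes, shape distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtrepair.mechanics import (
    FilamentShape,
    GridFlow,
    MechanicalParams,
    UniformFlow,
    equilibrium_shape,
    hydrodynamic_load,
    shape_distance,
)


def straight_shape(angle=0.0, n=21, ds=0.5):
    theta = np.full(n, angle)
    return FilamentShape.from_tangent_angles(theta, ds)


class TestFilamentShape:
    def test_validation_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            FilamentShape(np.zeros((2, 2)), 0.5)  # too few points
        pts = np.array([[0, 0], [1, 0], [2.5, 0]], dtype=float)
        with pytest.raises(ValueError, match="inextensibility"):
            FilamentShape(pts, 1.0)
        pts = np.array([[0, 0], [1, 0], [np.nan, 0]])
        with pytest.raises(ValueError):
            FilamentShape(pts, 1.0)

    def test_from_tangent_angles_exact_segments(self):
        rng = np.random.default_rng(3)
        theta = np.cumsum(rng.normal(0, 0.1, 40))
        shape = FilamentShape.from_tangent_angles(theta, 0.2)
        seg = np.linalg.norm(np.diff(shape.points, axis=0), axis=1)
        np.testing.assert_allclose(seg, 0.2, rtol=1e-12)
        assert shape.contour_length == pytest.approx(39 * 0.2)

    def test_resampling_restores_uniform_spacing(self):
        # non-uniformly sampled quarter circle
        t = np.linspace(0, np.pi / 2, 37) ** 1.3 / (np.pi / 2) ** 0.3
        pts = np.column_stack([np.cos(t), np.sin(t)])
        shape = FilamentShape.from_points_resampled(pts, n_points=50)
        seg = np.linalg.norm(np.diff(shape.points, axis=0), axis=1)
        np.testing.assert_allclose(seg, shape.segment_length, rtol=1e-9)
        # arc length of the quarter circle is pi/2
        assert shape.contour_length == pytest.approx(np.pi / 2, rel=1e-3)


class TestHydrodynamicLoad:
    def test_parallel_flow_half_drag(self):
        shape = straight_shape(angle=0.0)
        params = MechanicalParams(kappa=1.0, mu=1e-3, g=1.0)
        load = hydrodynamic_load(shape, UniformFlow(10.0, 0.0), params)
        np.testing.assert_allclose(load[:, 0], 1e-3 * 10.0 / 2.0)
        np.testing.assert_allclose(load[:, 1], 0.0, atol=1e-15)

    def test_perpendicular_flow_full_drag(self):
        shape = straight_shape(angle=0.0)
        params = MechanicalParams(kappa=1.0, mu=1e-3, g=1.0)
        load = hydrodynamic_load(shape, UniformFlow(0.0, 10.0), params)
        np.testing.assert_allclose(load[:, 1], 1e-3 * 10.0)
        np.testing.assert_allclose(load[:, 0], 0.0, atol=1e-15)

    def test_anisotropy_ratio_exactly_two(self):
        shape = straight_shape(angle=0.3)
        params = MechanicalParams(kappa=1.0, mu=1e-3, g=1.7)
        t = np.array([np.cos(0.3), np.sin(0.3)])
        n = np.array([-np.sin(0.3), np.cos(0.3)])
        v = 25.0
        perp = hydrodynamic_load(shape, UniformFlow(*(v * n)), params)
        para = hydrodynamic_load(shape, UniformFlow(*(v * t)), params)
        ratio = np.linalg.norm(perp, axis=1) / np.linalg.norm(para, axis=1)
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-12)

    def test_45_degree_projection(self):
        # tangent at 45 deg to a flow (0, v): load = g*mu*(-v/4, 3v/4)
        shape = straight_shape(angle=np.pi / 4)
        params = MechanicalParams(kappa=1.0, mu=1e-3, g=1.0)
        v = 8.0
        load = hydrodynamic_load(shape, UniformFlow(0.0, v), params)
        np.testing.assert_allclose(
            load, np.broadcast_to(1e-3 * np.array([-v / 4, 3 * v / 4]),
                                  load.shape), rtol=1e-12
        )

    def test_grid_flow_out_of_bounds_is_domain_error(self):
        grid = GridFlow([0.0, 1.0], [0.0, 1.0], np.ones((2, 2)),
                        np.zeros((2, 2)))
        shape = straight_shape(n=21, ds=0.5)  # extends to x = 10
        params = MechanicalParams(kappa=1.0)
        with pytest.raises(ValueError):
            hydrodynamic_load(shape, grid, params)


class TestEquilibriumShape:
    def test_zero_flow_is_straight(self):
        params = MechanicalParams(kappa=10.0, clamp_angle=0.4)
        sol = equilibrium_shape(params, 8.0, UniformFlow(0.0, 0.0), n_nodes=21)
        assert sol.converged and sol.residual_norm == 0.0
        np.testing.assert_allclose(sol.tangent_angles, 0.4)

    def test_small_deflection_matches_cantilever(self):
        # kappa = 100 pN*um^2, f = g*mu*v = 1e-3 pN/um, L = 10 um
        params = MechanicalParams(kappa=100.0)
        flow = UniformFlow(0.0, 10.0)
        sol = equilibrium_shape(params, 10.0, flow, n_nodes=61)
        s = sol.shape.arc_lengths
        L, f, k = 10.0, 1e-2, 100.0
        y_analytic = f * s**2 * (6 * L**2 - 4 * L * s + s**2) / (24 * k)
        tip = f * L**4 / (8 * k)
        assert sol.shape.points[-1, 1] == pytest.approx(tip, rel=0.02)
        assert np.max(np.abs(sol.shape.points[:, 1] - y_analytic)) < 0.02 * tip

    def test_homogeneity_in_kappa_and_mu(self, perp_flow):
        p1 = MechanicalParams(kappa=50.0, mu=1e-3)
        p2 = MechanicalParams(kappa=500.0, mu=1e-2)
        s1 = equilibrium_shape(p1, 10.0, perp_flow, n_nodes=41)
        s2 = equilibrium_shape(p2, 10.0, perp_flow, n_nodes=41)
        np.testing.assert_allclose(s1.shape.points, s2.shape.points,
                                   atol=1e-8)

    def test_reflection_symmetry(self):
        params = MechanicalParams(kappa=30.0)
        up = equilibrium_shape(params, 10.0, UniformFlow(0.0, 80.0),
                               n_nodes=41)
        down = equilibrium_shape(params, 10.0, UniformFlow(0.0, -80.0),
                                 n_nodes=41)
        np.testing.assert_allclose(up.shape.points[:, 0],
                                   down.shape.points[:, 0], atol=1e-8)
        np.testing.assert_allclose(up.shape.points[:, 1],
                                   -down.shape.points[:, 1], atol=1e-8)

    def test_grid_convergence_of_tip_position(self, default_params, perp_flow):
        tip = {}
        for n in (41, 81):
            sol = equilibrium_shape(default_params, 10.0, perp_flow,
                                    n_nodes=n)
            tip[n] = sol.shape.points[-1]
        assert np.linalg.norm(tip[81] - tip[41]) < 0.005 * 10.0

    def test_strongly_bent_shape_converges(self):
        # low rigidity, fast flow: hook-like shape, needs continuation
        params = MechanicalParams(kappa=5.0)
        sol = equilibrium_shape(params, 10.0, UniformFlow(0.0, 150.0),
                                n_nodes=61)
        assert sol.converged
        # tip swings past 60 degrees
        assert np.degrees(sol.tangent_angles[-1]) > 60

    def test_tension_vanishes_at_free_end(self, bent_shape):
        assert bent_shape.internal_tension[-1] == pytest.approx(0.0, abs=1e-12)


class TestShapeDistance:
    def test_identical_shapes_zero(self, bent_shape):
        assert shape_distance(bent_shape.shape, bent_shape.shape) == 0.0

    @given(
        dx=st.floats(-2, 2, allow_nan=False),
        dy=st.floats(-2, 2, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_rigid_translation_gives_d_squared(self, dx, dy):
        shape = straight_shape(n=31, ds=0.25)
        moved = FilamentShape(shape.points + [dx, dy], shape.segment_length)
        d2 = shape_distance(shape, moved)
        assert d2 == pytest.approx(dx * dx + dy * dy, abs=1e-12)
        assert shape_distance(moved, shape) == pytest.approx(d2)

    def test_incompatible_lengths_rejected(self):
        a = straight_shape(n=21, ds=0.5)
        b = straight_shape(n=21, ds=0.6)
        with pytest.raises(ValueError, match="contour lengths"):
            shape_distance(a, b)

    def test_quartic_curves_match_fine_grid_quadrature(self):
        # two near-straight curves with quartic transverse offsets; the
        # independent oracle is a 1e5-node quadrature of the analytic
        # squared difference
        L, n = 10.0, 101
        s = np.linspace(0, L, n)

        def ya(x):
            return 1e-3 * x**2 * (L - x) ** 2 / L**3

        def yb(x):
            return 1e-3 * (x**4 / L**3 - 0.5 * x**2 / L) / 2.0

        a = FilamentShape(np.column_stack([s, ya(s)]), L / (n - 1), rtol=0.01)
        b = FilamentShape(np.column_stack([s, yb(s)]), L / (n - 1), rtol=0.01)
        got = shape_distance(a, b)
        fine = np.linspace(0, L, 100001)
        oracle = np.trapezoid((ya(fine) - yb(fine)) ** 2, fine) / L
        assert got == pytest.approx(oracle, rel=1e-3)
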