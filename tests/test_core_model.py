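"""Vector field, Jacobian, equilibria, Hopf threshold, and integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlr4traffic import (
    DEFAULT_INIT,
    FIG2_BASE,
    DivergenceError,
    IntegrationConfig,
    State,
    TrafficParams,
    Trajectory,
    fixed_points,
    hopf_threshold,
    integrate,
    jacobian,
    vector_field,
)
from conftest import sample_params


class TestVectorField:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (State(0, 0, 0), (0.0, 0.0, 0.0)),  # origin is an equilibrium
            (State(1, 1, 1), (0.2, -3.8, -0.1)),  # hand substitution
            (State(-1, -1, 1), (-0.2, 3.8, -0.1)),  # mirrored by symmetry
        ],
    )
    def test_hand_computed_values(self, base_params, state, expected):
        assert vector_field(state, base_params) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonfinite_state(self, base_params):
        with pytest.raises(ValueError):
            State(float("nan"), 0.0, 0.0)
        with pytest.raises(ValueError):
            State(0.0, float("inf"), 0.0)

    @given(
        x=st.floats(-10, 10), y=st.floats(-10, 10), z=st.floats(-10, 10),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_mirror_equivariance(self, x, y, z, seed):
        """f(-x,-y,z) = (-f_x, -f_y, f_z) for every state and parameter set."""
        p = sample_params(np.random.default_rng(seed))
        fx, fy, fz = vector_field(State(x, y, z), p)
        gx, gy, gz = vector_field(State(-x, -y, z), p)
        assert (gx, gy, gz) == (-fx, -fy, fz)


class TestParamsValidation:
    def test_rejects_nondissipative_surface_pool(self):
        with pytest.raises(ValueError, match="gamma - sigma"):
            TrafficParams(phi=1.0, beta=1.0, alpha=1.0, gamma=1.0, sigma=1.5)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            TrafficParams(phi=-0.1, beta=1.0, alpha=1.0, gamma=2.0, sigma=1.0)

    def test_rejects_zero_endosome_exit(self):
        with pytest.raises(ValueError, match="beta \\+ alpha"):
            TrafficParams(phi=1.0, beta=0.0, alpha=0.0, gamma=2.0, sigma=1.0)


class TestJacobian:
    def test_lower_triangular_at_origin(self, base_params):
        """With y = z = 0 the matrix is lower triangular, so its diagonal
        (phi, -(beta+alpha), -(gamma-sigma)) = (1.2, -4.8, -1.1) gives the
        eigenvalues directly."""
        J = jacobian(State(0, 0, 0), base_params)
        assert np.allclose(np.triu(J, 1), 0.0)
        assert np.allclose(np.diag(J), [1.2, -4.8, -1.1])

    def test_explicit_matrix_at_ones(self, base_params):
        J = jacobian(State(1, 1, 1), base_params)
        expected = np.array([[1.2, -1, -1], [1, -4.8, 0], [1, 1, -1.1]])
        assert np.allclose(J, expected)

    def test_trace_state_independent(self, base_params):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = State(*rng.uniform(-5, 5, 3))
            assert np.trace(jacobian(s, base_params)) == pytest.approx(-4.7)

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        p = sample_params(rng)
        s0 = rng.uniform(-2, 2, 3)
        J = jacobian(State(*s0), p)
        h = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            fp = np.array(vector_field(State(*(s0 + e)), p))
            fm = np.array(vector_field(State(*(s0 - e)), p))
            assert np.allclose(J[:, j], (fp - fm) / (2 * h), atol=1e-6)


class TestFixedPoints:
    def test_closed_form_at_base_rates(self, base_params):
        """y* = sqrt(phi(gamma-sigma)), x* = (beta+alpha)y*, z* = (beta+alpha)phi."""
        pts = fixed_points(base_params)
        assert len(pts) == 3
        y_star = math.sqrt(1.32)
        pos = [fp for fp in pts if fp.state.x > 0][0]
        assert pos.state.y == pytest.approx(y_star, rel=1e-12)
        assert pos.state.x == pytest.approx(4.8 * y_star, rel=1e-12)
        assert pos.state.z == pytest.approx(5.76, rel=1e-12)

    def test_phi_zero_gives_only_origin(self, base_params):
        p = TrafficParams(0.0, base_params.beta, base_params.alpha,
                          base_params.gamma, base_params.sigma)
        pts = fixed_points(p)
        assert len(pts) == 1
        assert pts[0].state.as_array() == pytest.approx(np.zeros(3))

    def test_set_closed_under_mirror_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = sample_params(rng)
            states = {tuple(np.round(fp.state.as_array(), 10)) for fp in fixed_points(p)}
            mirrored = {(-x, -y, z) for (x, y, z) in states}
            assert states == mirrored

    def test_residuals_below_certified_bound(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = sample_params(rng)
            for fp in fixed_points(p):
                assert np.linalg.norm(vector_field(fp.state, p)) <= 1e-10

    def test_stability_flag_matches_eigenvalues(self, base_params):
        for phi in (0.5, 3.0):
            for fp in fixed_points(base_params.with_phi(phi)):
                assert fp.stable == all(ev.real < 0 for ev in fp.eigenvalues)


class TestHopfThreshold:
    def test_closed_form_at_base_rates(self, base_params):
        assert hopf_threshold(base_params) == pytest.approx(5.9 / 3)

    def test_unit_threshold_when_rates_sum_to_three(self):
        # beta+alpha + gamma-sigma = 2.0 + 1.0 = 3 -> threshold 1
        p = TrafficParams(phi=1.0, beta=1.5, alpha=0.5, gamma=1.8, sigma=0.8)
        assert hopf_threshold(p) == pytest.approx(1.0)

    def test_depends_only_on_rate_sums(self, base_params):
        shifted = TrafficParams(
            base_params.phi, base_params.beta - 0.4, base_params.alpha + 0.4,
            base_params.gamma, base_params.sigma,
        )
        assert hopf_threshold(shifted) == pytest.approx(
            hopf_threshold(base_params), rel=1e-12
        )

    def test_stability_flips_across_threshold(self, base_params):
        phi_star = hopf_threshold(base_params)
        below = fixed_points(base_params.with_phi(phi_star - 0.1))
        above = fixed_points(base_params.with_phi(phi_star + 0.1))
        assert all(fp.stable for fp in below if abs(fp.state.x) > 0)
        assert not any(fp.stable for fp in above if abs(fp.state.x) > 0)


class TestIntegrate:
    def test_equilibrium_init_stays_at_origin(self, base_params):
        traj = integrate(base_params, State(0, 0, 0), t_end=10.0)
        assert np.max(np.abs(traj.states)) < 1e-12

    def test_uniform_output_grid(self, base_params):
        traj = integrate(base_params, DEFAULT_INIT, t_end=5.0)
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(5.0)
        assert np.allclose(np.diff(traj.times), 0.01)

    def test_deterministic(self, base_params):
        a = integrate(base_params, DEFAULT_INIT, t_end=20.0)
        b = integrate(base_params, DEFAULT_INIT, t_end=20.0)
        assert np.array_equal(a.states, b.states)

    def test_mirror_equivariant_trajectories(self):
        rng = np.random.default_rng(3)
        p = sample_params(rng)
        init = State(*rng.uniform(-1, 1, 3))
        fwd = integrate(p, init, t_end=20.0)
        mir = integrate(p, init.mirrored(), t_end=20.0)
        assert np.max(np.abs(mir.states - fwd.states * np.array([-1, -1, 1]))) < 1e-8

    def test_matches_fixed_step_rk4_oracle(self, base_params):
        from conftest import rk4_endpoint

        traj = integrate(base_params, DEFAULT_INIT, t_end=50.0)
        oracle = rk4_endpoint(base_params, [0.1, 0.1, 0.1], 50.0, 1e-3)
        assert np.max(np.abs(traj.states[-1] - oracle)) < 1e-6

    def test_tolerance_halving_consistency(self, base_params):
        """Tightening tolerances moves the endpoint by far less than 10x
        the tighter relative tolerance (scaled by the state magnitude)."""
        loose = integrate(base_params, DEFAULT_INIT, 50.0, IntegrationConfig())
        tight = integrate(
            base_params, DEFAULT_INIT, 50.0, IntegrationConfig(rtol=5e-10, atol=5e-13)
        )
        scale = np.maximum(1.0, np.abs(tight.states[-1]))
        rel_change = np.max(np.abs(loose.states[-1] - tight.states[-1]) / scale)
        assert rel_change < 10 * 5e-10

    def test_overflow_guard_names_failing_time(self, base_params):
        # in the supra-threshold regime the orbit quickly exceeds a low guard
        cfg = IntegrationConfig(overflow=10.0)
        with pytest.raises(DivergenceError) as exc:
            integrate(base_params.with_phi(2.5), DEFAULT_INIT, 200.0, cfg)
        assert 0 < exc.value.t_fail < 200.0

    def test_rejects_nonpositive_horizon(self, base_params):
        with pytest.raises(ValueError):
            integrate(base_params, DEFAULT_INIT, t_end=0.0)


class TestTrajectory:
    def test_rejects_decreasing_times(self, base_params):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 1.0]), np.zeros((3, 3)), base_params)

    def test_rejects_nonfinite_states(self, base_params):
        states = np.zeros((3, 3))
        states[1, 1] = np.inf
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 2.0]), states, base_params)
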