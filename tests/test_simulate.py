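"""Integration, equilibration and phase portraits."""

import numpy as np
import pytest

from adaptivepi.equilibria import equilibrium_points
from adaptivepi.models import adaptive_pi_rhs
from adaptivepi.signals import make_step_schedule
from adaptivepi.simulate import (
    IntegrationError,
    integrate,
    phase_portrait,
    settle,
)

R, D = 11.0, 0.01


def rk4_oracle(params, x0, r, d, t_end, h):
    """Fixed-step classical Runge–Kutta, independent of the adaptive path."""
    n = int(round(t_end / h))
    state = np.asarray(x0, dtype=float)
    f = lambda t, x: adaptive_pi_rhs(t, x, params, r, d)
    t = 0.0
    for _ in range(n):
        k1 = f(t, state)
        k2 = f(t + h / 2, state + h / 2 * k1)
        k3 = f(t + h / 2, state + h / 2 * k2)
        k4 = f(t + h, state + h * k3)
        state = state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return state


class TestIntegrate:
    def test_equilibrium_persistence(self, baseline):
        _, e2 = equilibrium_points(baseline, R, D)
        traj = integrate(
            "adaptive_pi", baseline, np.array(e2.point), r=R, d=D,
            t_span=(0.0, 400.0), grid_step=0.5,
        )
        assert np.max(np.abs(traj.states - np.array(e2.point))) < 1e-6

    def test_convergence_to_tracking_equilibrium(self, baseline):
        traj = integrate(
            "adaptive_pi", baseline, (8.0, 2.0), r=R, d=D, t_span=(0.0, 100.0),
            grid_step=0.5,
        )
        np.testing.assert_allclose(traj.terminal_state, [11.000, 4.012], atol=1e-3)

    def test_matches_fixed_step_rk4(self, baseline):
        expected = rk4_oracle(baseline, (8.0, 2.0), R, D, t_end=10.0, h=1e-3)
        traj = integrate("adaptive_pi", baseline, (8.0, 2.0), r=R, d=D,
                         t_span=(0.0, 10.0), grid_step=0.1)
        np.testing.assert_allclose(traj.terminal_state, expected, atol=1e-5)

    def test_output_is_first_component(self, baseline):
        traj = integrate("adaptive_pi", baseline, (8.0, 2.0), r=R, d=D,
                         t_span=(0.0, 1.0), grid_step=0.1)
        np.testing.assert_array_equal(traj.output, traj.states[:, 0])

    def test_breakpoints_are_grid_points(self, baseline):
        r_sig, d_sig = make_step_schedule(seed=0)
        traj = integrate("adaptive_pi", baseline, (8.0, 2.0), r=r_sig, d=d_sig,
                         t_span=(0.0, 60.0), grid_step=0.01)
        assert 50.0 in traj.times
        # noise refresh times inside the varying interval are grid points too
        for t in (51.0, 52.0, 53.0):
            assert t in traj.times

    def test_zero_gain_axis_is_preserved(self, baseline):
        traj = integrate("adaptive_pi", baseline, (5.0, 0.0), r=R, d=D,
                         t_span=(0.0, 5.0), grid_step=0.1)
        assert np.max(np.abs(traj.states[:, 1])) <= 1e-12

    def test_solver_convergence_under_tolerance_halving(self, baseline):
        r_sig, d_sig = make_step_schedule(seed=0)
        kwargs = dict(r=r_sig, d=d_sig, t_span=(0.0, 150.0), grid_step=0.1)
        y1 = integrate("adaptive_pi", baseline, (8.0, 2.0), rtol=1e-8, atol=1e-10, **kwargs).output
        y2 = integrate("adaptive_pi", baseline, (8.0, 2.0), rtol=5e-9, atol=5e-11, **kwargs).output
        assert np.max(np.abs(y1 - y2)) < 10 * 1e-7

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_non_finite_state_raises(self, baseline):
        with pytest.raises(IntegrationError):
            integrate("adaptive_pi", baseline, (1e300, 0.0), r=R, d=D,
                      t_span=(0.0, 100.0), grid_step=1.0)

    def test_invalid_arguments(self, baseline):
        with pytest.raises(ValueError):
            integrate("adaptive_pi", baseline, (1.0, 1.0), t_span=(1.0, 1.0))
        with pytest.raises(ValueError):
            integrate("adaptive_pi", baseline, (1.0, 1.0), rtol=-1.0)
        with pytest.raises(ValueError):
            integrate("nope", baseline, (1.0, 1.0))

    def test_positivity_check_flags_excursions(self, baseline):
        traj = integrate("adaptive_pi", baseline, (5.0, 0.0), r=R, d=D,
                         t_span=(0.0, 2.0), grid_step=0.1)
        assert len(traj.positivity_violations()) == len(traj.times)  # z = 0 throughout

    def test_csv_export(self, baseline, tmp_path):
        traj = integrate("adaptive_pi", baseline, (8.0, 2.0), r=R, d=D,
                         t_span=(0.0, 1.0), grid_step=0.5)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        assert path.read_text().splitlines()[0] == "t,y,z"


class TestSettle:
    def test_already_settled(self, baseline):
        _, e2 = equilibrium_points(baseline, R, D)
        result = settle("adaptive_pi", baseline, np.array(e2.point), r0=R, d0=D)
        assert result.converged
        assert result.time == 0.0
        np.testing.assert_allclose(result.state, np.array(e2.point))

    def test_converges_from_nearby_state(self, baseline):
        result = settle("adaptive_pi", baseline, (10.0, 4.0), r0=R, d0=D,
                        horizon=500.0, tol=1e-6)
        assert result.converged
        np.testing.assert_allclose(result.state, [11.000, 4.012], atol=5e-4)

    def test_zero_gain_axis_never_settles(self, baseline):
        # on z = 0 the output grows exponentially: flagged, not silent
        result = settle("adaptive_pi", baseline, (1.0, 0.0), r0=R, d0=D,
                        horizon=200.0)
        assert not result.converged


class TestPhasePortrait:
    def test_trajectories_reach_tracking_equilibrium(self, baseline):
        _, e2 = equilibrium_points(baseline, R, D)
        pp = phase_portrait(baseline, R, D, y_range=(6.0, 14.0), z_range=(1.0, 6.0),
                            grid_n=4, horizon=60.0, grid_step=0.5)
        assert all(err is None for err in pp.errors)
        for traj in pp.trajectories:
            assert np.linalg.norm(traj.terminal_state - np.array(e2.point)) < 1e-2

    def test_grid_node_at_off_equilibrium_has_zero_field(self, baseline):
        e1, _ = equilibrium_points(baseline, R, D)
        pp = phase_portrait(baseline, R, D, y_range=(e1.y, 10.0), z_range=(0.0, 4.0),
                            grid_n=2, horizon=1.0, grid_step=0.5)
        np.testing.assert_allclose(pp.field[0, 0], [0.0, 0.0], atol=1e-14)

    def test_gain_scale_moves_gain_state_not_output(self, baseline):
        """s = 0.25 vs 1.5: same terminal output y = r, gain state 6x apart."""
        kwargs = dict(y_range=(8.0, 12.0), z_range=(2.0, 5.0), grid_n=2,
                      horizon=80.0, grid_step=0.5)
        pp_lo = phase_portrait(baseline, R, D, **kwargs)
        pp_hi = phase_portrait(baseline.replace(s=1.5), R, D, **kwargs)
        for a, b in zip(pp_lo.trajectories, pp_hi.trajectories):
            assert abs(a.terminal_state[0] - 11.0) < 1e-3
            assert abs(b.terminal_state[0] - 11.0) < 1e-3
        z_lo = pp_lo.equilibria[1].z
        z_hi = pp_hi.equilibria[1].z
        assert z_lo / z_hi == pytest.approx(6.0)

    def test_small_grid_rejected(self, baseline):
        with pytest.raises(ValueError):
            phase_portrait(baseline, R, D, grid_n=1)
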