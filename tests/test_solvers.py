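"""Fractional (delay) solvers against closed-form and cross-method oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fracosc import (FDESystemSpec, HistorySpec, TimeGrid, mittag_leffler,
                     solve_fde, solve_fdde)

RELAX = lambda t, x, d, p: -x  # D^alpha x = -x


class TestSolveFDE:
    def test_classical_exponential_decay(self):
        spec = FDESystemSpec(1, RELAX, alpha=1.0)
        grid = TimeGrid(h=0.01, n_steps=100)
        for method in ("abm", "oustaloup"):
            tr = solve_fde(spec, [1.0], grid, method=method)
            assert abs(tr.states[-1, 0] - np.exp(-1.0)) < 1e-3
        # reference scheme meets the tighter classical tolerance
        tr = solve_fde(spec, [1.0], grid, method="abm")
        assert abs(tr.states[-1, 0] - np.exp(-1.0)) < 1e-4

    def test_fractional_relaxation_matches_mittag_leffler(self):
        spec = FDESystemSpec(1, RELAX, alpha=0.7)
        grid = TimeGrid(h=0.01, n_steps=500)
        tr = solve_fde(spec, [1.0], grid)
        exact = mittag_leffler(0.7, -grid.times ** 0.7)
        assert np.max(np.abs(tr.states[:, 0] - exact)) < 1e-2

    def test_methods_agree_on_fractional_problem(self):
        spec = FDESystemSpec(1, RELAX, alpha=0.7)
        grid = TimeGrid(h=0.01, n_steps=500)
        a = solve_fde(spec, [1.0], grid, method="abm").states
        o = solve_fde(spec, [1.0], grid, method="oustaloup").states
        assert np.max(np.abs(a - o)) < 5e-3  # documented cross-method tolerance

    def test_initial_state_is_reproduced(self):
        spec = FDESystemSpec(2, lambda t, x, d, p: -x, alpha=0.8)
        tr = solve_fde(spec, [2.0, -1.0], TimeGrid(h=0.05, n_steps=20))
        assert np.array_equal(tr.states[0], [2.0, -1.0])

    def test_abm_error_shrinks_monotonically_with_step(self):
        errs = []
        for h in (0.04, 0.02, 0.01):
            grid = TimeGrid(h=h, n_steps=int(round(2.0 / h)))
            spec = FDESystemSpec(1, RELAX, alpha=0.6)
            tr = solve_fde(spec, [1.0], grid)
            exact = mittag_leffler(0.6, -grid.times ** 0.6)
            errs.append(np.max(np.abs(tr.states[:, 0] - exact)))
        assert errs[0] > errs[1] > errs[2]

    def test_alpha_one_matches_classical_integrator_on_rossler(self):
        from fracosc import RosslerParams, rossler_system
        spec = rossler_system(RosslerParams(alpha=1.0))
        grid = TimeGrid(h=0.005, n_steps=2000)  # 10 time units
        tr = solve_fde(spec, [1.0, 1.0, 1.0], grid)
        ref = solve_ivp(lambda t, s: spec(t, s), [0, grid.t_end], [1.0, 1.0, 1.0],
                        t_eval=grid.times, rtol=1e-10, atol=1e-12, method="DOP853")
        rel = np.max(np.abs(tr.states - ref.y.T)) / np.max(np.abs(ref.y))
        assert rel < 1e-4

    def test_blowup_is_flagged_not_raised(self):
        spec = FDESystemSpec(1, lambda t, x, d, p: x ** 2, alpha=1.0)
        tr = solve_fde(spec, [5.0], TimeGrid(h=0.05, n_steps=200))
        assert tr.blown_up
        assert tr.states.shape[0] < 201
        assert np.all(np.isfinite(tr.states))

    def test_delayed_spec_rejected(self):
        spec = FDESystemSpec(1, RELAX, alpha=1.0, delay=1.0)
        with pytest.raises(ValueError, match="solve_fdde"):
            solve_fde(spec, [1.0], TimeGrid(h=0.01, n_steps=10))


class TestSolveFDDE:
    def test_linear_delay_problem_matches_method_of_steps(self):
        # x'(t) = -x(t-1), x == 1 on [-1, 0]: piecewise polynomial solution
        spec = FDESystemSpec(1, lambda t, x, d, p: -d, alpha=1.0, delay=1.0)
        grid = TimeGrid(h=0.01, n_steps=200)
        tr = solve_fdde(spec, HistorySpec.constant([1.0]), grid)
        t = grid.times
        exact = np.where(t <= 1, 1 - t, (1 - t) + 0.5 * (t - 1) ** 2)
        assert np.max(np.abs(tr.states[:, 0] - exact)) < 1e-4

    def test_tiny_delay_approaches_undelayed_solution(self):
        grid = TimeGrid(h=0.01, n_steps=300)
        free = solve_fde(FDESystemSpec(1, RELAX, alpha=0.9), [1.0], grid)
        tiny = solve_fdde(
            FDESystemSpec(1, lambda t, x, d, p: -d, alpha=0.9, delay=0.01),
            HistorySpec.constant([1.0]), grid)
        assert np.max(np.abs(free.states - tiny.states)) < 2e-2

    def test_delay_below_step_rejected(self):
        spec = FDESystemSpec(1, lambda t, x, d, p: -d, alpha=1.0, delay=0.001)
        with pytest.raises(ValueError, match="step"):
            solve_fdde(spec, HistorySpec.constant([1.0]), TimeGrid(h=0.01, n_steps=10))

    def test_undelayed_spec_rejected(self):
        spec = FDESystemSpec(1, RELAX, alpha=1.0)
        with pytest.raises(ValueError, match="solve_fde"):
            solve_fdde(spec, HistorySpec.constant([1.0]), TimeGrid(h=0.01, n_steps=10))

    def test_function_history_is_honored(self):
        # history x(t) = 1 + t on [-1, 0]; first interval integrates it exactly
        spec = FDESystemSpec(1, lambda t, x, d, p: -d, alpha=1.0, delay=1.0)
        grid = TimeGrid(h=0.01, n_steps=100)
        hist = HistorySpec(function=lambda t: np.array([1.0 + t]))
        tr = solve_fdde(spec, hist, grid)
        t = grid.times
        # x(t) = x(0) - int_0^t (1 + (s - 1)) ds = 1 - t^2/2 on [0, 1]
        exact = 1.0 - t ** 2 / 2
        assert np.max(np.abs(tr.states[:, 0] - exact)) < 1e-4

    def test_alpha_one_agrees_with_classical_dde_on_goodwin(self):
        # cross-check the full delayed Goodwin right-hand side against a
        # method-of-steps integration built on solve_ivp
        from fracosc import GoodwinParams, fractional_delay_goodwin
        p = GoodwinParams(n=10.0, k2=0.1, tau=5.0, alpha=1.0)
        spec = fractional_delay_goodwin(p)
        grid = TimeGrid(h=0.01, n_steps=1500)  # [0, 15] = 3 delay intervals
        tr = solve_fdde(spec, HistorySpec.constant([0.1]), grid)

        # method of steps: integrate interval by interval with dense history
        from scipy.interpolate import interp1d
        t_hist = np.array([-p.tau, 0.0])
        x_hist = np.array([0.1, 0.1])
        hist = interp1d(t_hist, x_hist, fill_value="extrapolate")
        for k in range(3):
            def rhs(t, x, h=hist):
                return [1.0 / (1.0 + float(h(t - p.tau)) ** p.n) - p.k2 * x[0]]
            seg = solve_ivp(rhs, [k * p.tau, (k + 1) * p.tau], [float(hist(k * p.tau))],
                            dense_output=True, rtol=1e-10, atol=1e-12)
            ts = np.linspace(k * p.tau, (k + 1) * p.tau, 501)
            t_hist = np.concatenate([t_hist, ts])
            x_hist = np.concatenate([x_hist, seg.sol(ts)[0]])
            hist = interp1d(t_hist, x_hist, fill_value="extrapolate")
        ref = interp1d(t_hist, x_hist)(grid.times)
        assert np.max(np.abs(tr.states[:, 0] - ref)) < 1e-4
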