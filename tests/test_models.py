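"""Goodwin/Rössler model definitions and the reinitiation-survival law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracosc import (GoodwinParams, HistorySpec, ReinitiationModel,
                     RosslerParams, TimeGrid, fractional_delay_goodwin,
                     goodwin_rhs, hill_repression, preset_spec,
                     reinitiation_survival, rossler_system, solve_fde,
                     solve_fdde)
from fracosc.dynamics import goodwin_fixed_point
from fracosc.models import rossler_equilibria


class TestHillRepression:
    def test_no_repressor_gives_full_synthesis(self):
        assert hill_repression(0.0, 9) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [1, 2, 9, 10.5])
    def test_half_maximal_point(self, n):
        assert hill_repression(1.0, n) == pytest.approx(0.5)

    def test_strong_repression_value(self):
        assert hill_repression(2.0, 9) == pytest.approx(1.0 / 513.0)

    def test_large_n_approaches_step_at_one(self):
        assert hill_repression(0.9, 200) > 0.99
        assert hill_repression(1.1, 200) < 0.01

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_repression(-0.1, 2)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(x=st.floats(0.0, 50.0), n=st.floats(1.0, 20.0))
    def test_bounded_in_unit_interval(self, x, n):
        v = hill_repression(x, n)
        assert 0.0 < v <= 1.0

    def test_monotone_non_increasing(self):
        x = np.linspace(0.0, 5.0, 200)
        assert np.all(np.diff(hill_repression(x, 8)) <= 0)


class TestGoodwinRHS:
    def test_one_dim_form(self):
        p = GoodwinParams(n=10, k2=0.1)
        assert goodwin_rhs([0.0], p)[0] == pytest.approx(1.0)
        x_star = goodwin_fixed_point(p)
        assert goodwin_rhs([x_star], p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_dim_chain_structure(self):
        p = GoodwinParams(n=2, k2=0.5)
        out = goodwin_rhs([1.0, 2.0, 3.0], p)
        assert out[0] == pytest.approx(hill_repression(3.0, 2) - 0.5 * 1.0)
        assert out[1] == pytest.approx(1.0 - 0.5 * 2.0)
        assert out[2] == pytest.approx(2.0 - 0.5 * 3.0)

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError):
            goodwin_rhs([1.0, 1.0, 1.0, 1.0], GoodwinParams())


class TestFractionalDelayGoodwin:
    def test_reduces_to_classical_model_without_delay_and_memory(self):
        spec = fractional_delay_goodwin(GoodwinParams(n=10, k2=0.1, tau=0.0, alpha=1.0))
        assert spec.delay == 0.0 and spec.alpha == 1.0 and spec.dimension == 1
        out = spec(0.0, np.array([0.5]), None)
        assert out[0] == pytest.approx(1 / (1 + 0.5 ** 10) - 0.1 * 0.5)

    def test_delay_acts_only_in_synthesis_term(self):
        spec = fractional_delay_goodwin(GoodwinParams(n=2, k2=0.5, tau=3.0))
        present, delayed = np.array([2.0]), np.array([0.0])
        out = spec(0.0, present, delayed)
        # synthesis sees the delayed value (full rate), degradation the present
        assert out[0] == pytest.approx(1.0 - 0.5 * 2.0)

    def test_classical_limit_converges_to_unique_root(self):
        # alpha=1, tau=0: no sustained oscillation, trajectory settles on
        # the root of 1/(1+x^n) = k2 x from either side
        p = GoodwinParams(n=10, k2=0.1, tau=0.0, alpha=1.0)
        spec = fractional_delay_goodwin(p)
        x_star = goodwin_fixed_point(p)
        grid = TimeGrid(h=0.01, n_steps=20000)
        for x0 in (0.0, 5.0):
            tr = solve_fde(spec, [x0], grid)
            assert abs(tr.states[-1, 0] - x_star) < 1e-3

    def test_nonnegativity_from_nonnegative_history(self):
        spec = fractional_delay_goodwin(GoodwinParams(tau=20.0, alpha=0.9))
        tr = solve_fdde(spec, HistorySpec.constant([0.1]),
                        TimeGrid(h=0.02, n_steps=25000))
        assert tr.states.min() > -1e-6


class TestRosslerSystem:
    def test_vector_field(self):
        spec = rossler_system(RosslerParams(a=0.15, b=0.2, c=10.0))
        out = spec(0.0, np.array([1.0, 2.0, 3.0]), None)
        assert np.allclose(out, [-5.0, 1.3, 0.2 + 3.0 * (1.0 - 10.0)])

    def test_equilibria_are_roots_of_the_flow(self):
        p = RosslerParams()
        spec = rossler_system(p)
        for eq in rossler_equilibria(p):
            assert np.allclose(spec(0.0, eq, None), 0.0, atol=1e-10)

    def test_commensurate_order_is_shared(self):
        spec = rossler_system(RosslerParams(alpha=0.93))
        assert spec.alpha == 0.93  # single order for all three equations

    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError):
            RosslerParams(c=-1.0)


class TestReinitiationSurvival:
    def test_certain_survival_at_zero_interval(self):
        assert reinitiation_survival(ReinitiationModel(gamma=2.0), 0.0) == 1.0

    def test_half_life(self):
        m = ReinitiationModel(gamma=1.0)
        assert reinitiation_survival(m, np.log(2.0)) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(t1=st.floats(0.0, 20.0), t2=st.floats(0.0, 20.0),
           gamma=st.floats(0.01, 5.0))
    def test_memoryless_factorization(self, t1, t2, gamma):
        m = ReinitiationModel(gamma=gamma)
        assert reinitiation_survival(m, t1 + t2) == pytest.approx(
            reinitiation_survival(m, t1) * reinitiation_survival(m, t2), rel=1e-12)

    def test_log_linear_strictly_decreasing(self):
        m = ReinitiationModel(gamma=0.3)
        t = np.linspace(0.0, 10.0, 50)
        s = reinitiation_survival(m, t)
        assert np.all(np.diff(s) < 0)
        assert np.allclose(np.diff(np.log(s)), -0.3 * np.diff(t), atol=1e-12)

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            reinitiation_survival(ReinitiationModel(), -1.0)


class TestParameterValidation:
    def test_order_range_enforced(self):
        with pytest.raises(ValueError):
            GoodwinParams(alpha=1.2)
        with pytest.raises(ValueError):
            RosslerParams(alpha=0.0)

    def test_synthesis_scale_is_pinned(self):
        with pytest.raises(ValueError):
            GoodwinParams(synthesis_scale=2.0)

    def test_presets_instantiate(self):
        for name in ("goodwin1", "goodwin3", "goodwin-frac-delay",
                     "rossler", "rossler-frac", "rossler-classic"):
            spec = preset_spec(name)
            assert spec.dimension in (1, 3)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            preset_spec("lorenz")
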