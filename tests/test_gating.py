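"""Mean-field gating: fixed points, critical coupling, activation curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coopna
from coopna.gating import (
    CoopGateParams,
    collective_activation_curve,
    critical_coupling,
    fixed_points,
    self_consistency_map,
    simulate_gate_step,
    steady_gate,
    threshold_sensitivity,
    threshold_voltage,
)


def gate(mu, k=6.0, q=1, v_half=-30.0, tau_m=0.1):
    return CoopGateParams(v_half=v_half, k=k, q=q, tau_m=tau_m, K=1, J=mu)


class TestSteadyGate:
    def test_boltzmann_values(self):
        p = gate(0.0)
        assert steady_gate(p.v_half, p) == pytest.approx(0.5)
        assert steady_gate(p.v_half + 20 * p.k, p) == pytest.approx(1.0, abs=1e-8)
        # direct evaluation at one slope factor above midpoint
        assert steady_gate(p.v_half + p.k, p) == pytest.approx(0.7310585786, abs=1e-9)

    @given(st.floats(-120, 60), st.floats(0.01, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_and_bounded(self, v, dv):
        p = gate(0.0)
        m1, m2 = steady_gate(v, p), steady_gate(v + dv, p)
        assert 0.0 < m1 < 1.0
        assert m1 < m2


class TestSelfConsistencyMap:
    def test_decoupled_limit_is_plain_boltzmann(self):
        p = gate(0.0)
        m = np.linspace(0, 1, 7)
        assert self_consistency_map(m, -40.0, 1.0, p) == pytest.approx(
            np.full(7, steady_gate(-40.0, p))
        )

    def test_no_open_neighbors(self):
        p = gate(48.0)
        assert self_consistency_map(0.0, -35.0, 1.0, p) == pytest.approx(
            steady_gate(-35.0, p)
        )

    def test_direct_evaluation_at_midpoint(self):
        # F(0.5) = m_inf(v_half + 48*0.5) = 1/(1+e^-4)
        p = gate(48.0)
        assert self_consistency_map(0.5, p.v_half, 1.0, p) == pytest.approx(
            0.9820137900, abs=1e-9
        )

    @given(
        st.floats(0, 1), st.floats(-80, 0), st.floats(0.1, 1.0),
        st.floats(0, 100), st.integers(1, 3),
    )
    @settings(deadline=None, max_examples=60)
    def test_self_map_monotone(self, m, v, a, mu, q):
        p = gate(mu, q=q)
        f = self_consistency_map(m, v, a, p)
        assert 0.0 < f < 1.0
        assert self_consistency_map(min(m + 0.1, 1.0), v, a, p) >= f


class TestFixedPoints:
    def test_decoupled_single_stable_root(self):
        p = gate(0.0)
        fp = fixed_points(-40.0, 1.0, p)
        assert len(fp.roots) == 1
        assert fp.stability[0]
        assert fp.roots[0] == pytest.approx(steady_gate(-40.0, p), abs=1e-9)

    def test_tangency_double_root_at_half(self):
        # at mu*a = 4k the fold degenerates: single root at m=1/2 with unit slope
        p = gate(24.0)
        v_tan = threshold_voltage(24.0, 1.0, p)
        fp = fixed_points(v_tan, 1.0, p)
        assert fp.roots == pytest.approx([0.5], abs=1e-4)

    def test_three_roots_outer_stable(self):
        p = gate(48.0)
        fp = fixed_points(-48.0, 1.0, p)  # inside the bistable window
        assert len(fp.roots) == 3
        assert list(fp.stability) == [True, False, True]

    @given(st.floats(-80, -10), st.floats(0, 120), st.floats(0.2, 1.0))
    @settings(deadline=None, max_examples=40)
    def test_root_count_and_alternating_stability(self, v, mu, a):
        fp = fixed_points(v, a, gate(mu))
        assert 1 <= len(fp.roots) <= 3
        assert np.all(np.diff(fp.roots) > 0)
        if len(fp.roots) == 3:
            assert list(fp.stability) == [True, False, True]


class TestCriticalCoupling:
    @pytest.mark.parametrize(
        "k,a", [(6.0, 1.0), (3.0, 1.0), (6.0, 0.5)],
    )
    def test_closed_form_matches_numeric_scan(self, k, a):
        p = gate(0.0, k=k)
        mu_closed = critical_coupling(a, p)
        assert mu_closed == pytest.approx(4.0 * k / a)
        mu_num = critical_coupling(a, p, method="numeric")
        assert mu_num == pytest.approx(mu_closed, rel=1e-4)

    def test_numeric_path_for_delayed_activation(self):
        # q = 3: tangency min of k/(a q m^q (1-m)) gives k (q+1)^(q+1)/q^(q+1)
        p = gate(0.0, q=3)
        expected = 6.0 * 4.0**4 / 3.0**4
        assert critical_coupling(1.0, p, method="numeric") == pytest.approx(
            expected, rel=1e-4
        )

    def test_no_available_channels_is_an_error(self):
        with pytest.raises(ValueError):
            critical_coupling(0.0, gate(0.0))


class TestThresholdVoltage:
    def test_exactly_critical(self):
        p = gate(24.0)
        assert threshold_voltage(24.0, 1.0, p) == pytest.approx(p.v_half - 12.0)

    def test_strong_coupling_closed_form(self):
        p = gate(48.0)
        # m_sn = (1 - sqrt(1 - 4k/(mu a)))/2, V* = v_half + k logit(m_sn) - mu a m_sn
        m_sn = 0.5 * (1 - np.sqrt(1 - 24.0 / 48.0))
        expected = p.v_half + 6.0 * np.log(m_sn / (1 - m_sn)) - 48.0 * m_sn
        assert threshold_voltage(48.0, 1.0, p) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(p.v_half - 17.61, abs=0.01)

    def test_threshold_decreases_with_coupling(self):
        p = gate(0.0)
        v = [threshold_voltage(mu, 1.0, p) for mu in (30.0, 36.0, 48.0)]
        assert v[2] < v[1] < v[0]

    def test_subcritical_raises(self):
        with pytest.raises(ValueError, match="critical"):
            threshold_voltage(20.0, 1.0, gate(0.0))


class TestThresholdSensitivity:
    def test_strong_coupling_asymptote_is_minus_k(self):
        p = gate(0.0)
        mu_c = critical_coupling(1.0, p)
        s = threshold_sensitivity(20 * mu_c, 1.0, p)
        assert s == pytest.approx(-p.k, rel=0.05)

    def test_coupling_independence(self):
        p = gate(0.0)
        mu_c = critical_coupling(1.0, p)
        s20 = threshold_sensitivity(20 * mu_c, 1.0, p)
        s40 = threshold_sensitivity(40 * mu_c, 1.0, p)
        assert abs(s40 - s20) / abs(s20) < 0.02

    def test_integrated_shift_for_ten_percent_inactivation(self):
        # V*(a=0.9) - V*(a=1) should match -k ln(0.9) in the strong-coupling limit
        p = gate(0.0)
        mu = 20 * critical_coupling(1.0, p)
        shift = threshold_voltage(mu, 0.9, p) - threshold_voltage(mu, 1.0, p)
        assert shift == pytest.approx(-p.k * np.log(0.9), rel=0.05)


class TestCollectiveActivationCurve:
    v_grid = np.arange(-75.0, 5.0, 0.1)

    def test_decoupled_equals_boltzmann(self):
        p = gate(0.0)
        res = collective_activation_curve(p, 1.0, self.v_grid)
        assert not res.discontinuous
        np.testing.assert_allclose(
            res.open_fraction, steady_gate(self.v_grid, p), atol=1e-8
        )

    def test_supercritical_jump_location_and_size(self):
        p = gate(36.0)  # 1.5 x critical
        res = collective_activation_curve(p, 1.0, self.v_grid)
        assert res.discontinuous
        assert res.jump_size > 0.5
        assert res.v_threshold == pytest.approx(
            threshold_voltage(36.0, 1.0, p), abs=0.05
        )

    def test_subcritical_continuous_and_increasing(self):
        p = gate(0.9 * 24.0)
        res = collective_activation_curve(p, 1.0, self.v_grid)
        assert not res.discontinuous
        assert np.all(np.diff(res.open_fraction) > 0)

    def test_hysteresis_between_branches(self):
        p = gate(48.0)
        fwd = collective_activation_curve(p, 1.0, self.v_grid, "forward")
        bwd = collective_activation_curve(p, 1.0, self.v_grid, "backward")
        assert fwd.discontinuous and bwd.discontinuous
        # backward jump (lower saddle-node of the upper branch) is more negative
        assert bwd.v_threshold < fwd.v_threshold
        inside = (self.v_grid > bwd.v_threshold + 0.2) & (
            self.v_grid < fwd.v_threshold - 0.2
        )
        outside = (self.v_grid < bwd.v_threshold - 0.2) | (
            self.v_grid > fwd.v_threshold + 0.2
        )
        assert np.max(np.abs(fwd.open_fraction[inside] - bwd.open_fraction[inside])) > 0.5
        np.testing.assert_allclose(
            fwd.open_fraction[outside], bwd.open_fraction[outside], atol=1e-6
        )

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            collective_activation_curve(gate(0.0), 1.0, np.array([0.0, -1.0, 1.0]))

    def test_csv_export_columns(self, tmp_path):
        res = collective_activation_curve(gate(0.0), 1.0, np.arange(-60, -20, 1.0))
        path = tmp_path / "curve.csv"
        res.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["voltage_mV", "open_fraction", "branch"]
        assert len(df) == len(res.v_grid)


class TestGateStepResponse:
    def test_decoupled_relaxation_is_monoexponential(self):
        p = gate(0.0)
        res = simulate_gate_step(-70.0, [-30.0], 1.0, p, dt=0.005, t_step=1.0)
        s = res.open_fraction[0]
        s_inf = steady_gate(-30.0, p)
        resid = s_inf - s
        mask = resid > 1e-6 * s_inf
        slope = np.polyfit(res.t[mask], np.log(resid[mask]), 1)[0]
        assert -1.0 / slope == pytest.approx(p.tau_m, rel=0.01)

    def test_terminal_value_matches_fixed_point(self):
        p = gate(30.0)
        res = simulate_gate_step(-70.0, [-38.0], 1.0, p, dt=0.005, t_step=20 * p.tau_m)
        fp = fixed_points(-38.0, 1.0, p)
        terminal = res.open_fraction[0][-1]
        # flow from the hold steady state reaches one of the stable roots
        assert min(abs(terminal - r) for r in fp.roots[fp.stability]) < 1e-6

    def test_all_or_none_around_jump(self):
        # well above critical the saddle-node sits at small m
        # (m_sn = (1 - sqrt(1 - 4k/(mu a)))/2 < 0.1 requires mu a > ~2.8 mu_c a),
        # so steps bracketing the jump voltage give nearly closed vs nearly open
        mu = 24.0 * 3.0
        p = gate(mu)
        v_thr = threshold_voltage(mu, 1.0, p)
        res = simulate_gate_step(
            -80.0, [v_thr - 0.5, v_thr + 0.5], 1.0, p, dt=0.005, t_step=60.0
        )
        below, above = res.open_fraction[0][-1], res.open_fraction[1][-1]
        assert below < 0.1
        assert above > 0.9

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_gate_step(-70.0, [-30.0], 1.0, gate(0.0), dt=0.05, t_step=1.0)

    @given(st.floats(0, 80), st.floats(-80, -20))
    @settings(deadline=None, max_examples=10)
    def test_open_fraction_stays_in_unit_interval(self, mu, v_step):
        res = simulate_gate_step(-75.0, [v_step], 0.8, gate(mu), dt=0.01, t_step=2.0)
        assert np.all(res.open_fraction >= 0.0)
        assert np.all(res.open_fraction <= 0.8 + 1e-12)


def test_params_validation():
    with pytest.raises(ValueError):
        CoopGateParams(k=-1.0)
    with pytest.raises(ValueError):
        CoopGateParams(q=0)
    with pytest.raises(ValueError):
        CoopGateParams(J=-2.0)
    p = CoopGateParams(K=4, J=3.0)
    assert p.mu == 12.0
    assert p.with_mu(30.0).mu == 30.0
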