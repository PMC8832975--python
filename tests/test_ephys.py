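"""IV extraction, reversal potential, Boltzmann/exponential fits, and the
noiseless pipeline-identity property."""

import numpy as np
import pytest

from famseg.cohort import SweepSet
from famseg.ephys import (
    IVCurve,
    activation_curve,
    analyze_cell,
    build_iv,
    deactivation_tau,
    estimate_vrev,
    fit_boltzmann,
    fit_single_exponential,
    inactivation_tau,
    peak_current,
    ssi_curve,
)
from .conftest import noiseless_sweepset


class TestPeakCurrent:
    def test_constant_trace(self):
        t = np.arange(100) * 0.1
        assert peak_current(t, np.full(100, -5.0), (0, 10)) == -5.0

    def test_outward_sign_preserved(self):
        t = np.arange(100) * 0.1
        assert peak_current(t, np.full(100, 3.0), (0, 10)) == pytest.approx(3.0)

    def test_empty_window_raises(self):
        t = np.arange(100) * 0.1
        with pytest.raises(ValueError, match="empty"):
            peak_current(t, np.zeros(100), (50, 60))

    def test_matches_simulator_analytic_peak(self, wt_iv_cell):
        """Noiseless +20 mV sweep: extracted peak within 1% of the analytic
        gate-product maximum."""
        p = wt_iv_cell.truth
        proto = wt_iv_cell.protocol
        got = peak_current(wt_iv_cell.time_ms, wt_iv_cell.sweep(20.0), proto.test_window())
        tl = np.linspace(0, 20.0, 200_001)
        m = p.m_inf(20.0) + (p.m_inf(-80.0) - p.m_inf(20.0)) * np.exp(-tl / p.tau_act)
        h = p.h_inf(20.0) + (p.h_inf(-80.0) - p.h_inf(20.0)) * np.exp(-tl / p.tau_inact)
        i = p.gmax_density * wt_iv_cell.capacitance_pF * m * h * (20.0 - p.vrev)
        expected = i[np.argmax(np.abs(i))]
        assert got == pytest.approx(expected, rel=0.01)


class TestBuildIV:
    def test_density_arithmetic(self, wt_iv_cell):
        iv15 = build_iv(wt_iv_cell)
        double = SweepSet(
            cell_id="x2", group="WT", protocol=wt_iv_cell.protocol,
            capacitance_pF=30.0, time_ms=wt_iv_cell.time_ms,
            sweeps=wt_iv_cell.sweeps,
        )
        iv30 = build_iv(double)
        np.testing.assert_allclose(iv30.current_density, iv15.current_density / 2)

    def test_missing_level_named(self, wt_iv_cell):
        sweeps = dict(wt_iv_cell.sweeps)
        sweeps.pop(20.0)
        broken = SweepSet(
            cell_id="b", group="WT", protocol=wt_iv_cell.protocol,
            capacitance_pF=15.0, time_ms=wt_iv_cell.time_ms, sweeps=sweeps,
        )
        with pytest.raises(ValueError, match="20"):
            build_iv(broken)

    def test_one_point_per_level_increasing(self, wt_iv_cell):
        iv = build_iv(wt_iv_cell)
        assert len(iv.v) == len(wt_iv_cell.protocol.sweep_levels)
        assert np.all(np.diff(iv.v) > 0)


class TestEstimateVrev:
    def test_exact_line_x_intercept(self):
        v = np.array([10.0, 15.0, 20.0, 25.0, 30.0])
        iv = IVCurve(v=v, current_density=0.5 * (v - 40.0))
        assert estimate_vrev(iv) == pytest.approx(40.0)

    def test_recovers_preset_within_one_mV(self, wt_iv_cell):
        iv = build_iv(wt_iv_cell)
        assert estimate_vrev(iv) == pytest.approx(wt_iv_cell.truth.vrev, abs=1.0)

    def test_two_points_rejected(self):
        iv = IVCurve(v=np.array([10.0, 30.0]), current_density=np.array([-1.0, 1.0]))
        with pytest.raises(ValueError, match=">= 3"):
            estimate_vrev(iv)

    def test_flat_curve_no_crossing(self):
        v = np.array([10.0, 15.0, 20.0, 25.0, 30.0])
        iv = IVCurve(v=v, current_density=np.full(5, -2.0))
        with pytest.raises(ValueError, match="no crossing"):
            estimate_vrev(iv)


class TestActivationCurve:
    def test_conductance_arithmetic(self):
        iv = IVCurve(
            v=np.array([-20.0, -10.0, 0.0, 10.0, 20.0]),
            current_density=np.array([-5.0, -10.0, -20.0, -18.0, -12.0]),
        )
        act = activation_curve(iv, vrev=40.0)
        # G at 0 mV is -20/(0-40) = 0.5; the max G here is -18/(10-40) = 0.6
        assert act.loc[act.v == 0.0, "g_norm"].item() == pytest.approx(0.5 / 0.6)

    def test_matches_simulator_m_inf(self, wt_iv_cell):
        """Noiseless identity: normalized conductance equals the gating
        steady state at each voltage within 1%."""
        p = wt_iv_cell.truth
        act = activation_curve(build_iv(wt_iv_cell), p.vrev)
        expect = p.m_inf(act["v"].to_numpy())
        expect = expect / expect.max()
        np.testing.assert_allclose(act["g_norm"], expect, atol=0.01)

    def test_all_zero_currents_rejected(self):
        iv = IVCurve(v=np.linspace(-60, 30, 19), current_density=np.zeros(19))
        with pytest.raises(ValueError, match="no inward conductance"):
            activation_curve(iv, vrev=40.0)


class TestFitBoltzmann:
    def test_exact_samples_recovered(self):
        from famseg.channel import gate_steady_state

        v = np.arange(-60.0, 31.0, 5.0)
        y = gate_steady_state(v, -1.0, 5.0, "activation")
        fit = fit_boltzmann(v, y, "activation")
        assert fit.converged
        assert fit.v50 == pytest.approx(-1.0, abs=1e-6)
        assert fit.k == pytest.approx(5.0, abs=1e-6)

    def test_inactivation_direction(self):
        from famseg.channel import gate_steady_state

        v = np.arange(-100.0, 31.0, 5.0)
        y = gate_steady_state(v, -35.7, 5.0, "inactivation")
        fit = fit_boltzmann(v, y, "inactivation")
        assert fit.converged and fit.v50 == pytest.approx(-35.7, abs=1e-6)

    def test_flat_input_not_converged(self):
        v = np.linspace(-60, 30, 19)
        fit = fit_boltzmann(v, np.zeros(19), "activation")
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            fit_boltzmann([0, 1, 2, 3], [0, 0.5, 0.7, 1.0], "activation")

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        v = np.arange(-60.0, 31.0, 5.0)
        y = 1 / (1 + np.exp((-1 - v) / 5)) + rng.normal(0, 0.02, v.size)
        f1 = fit_boltzmann(v, y, "activation")
        f2 = fit_boltzmann(v, y, "activation")
        assert (f1.v50, f1.k) == (f2.v50, f2.k)


class TestSSICurve:
    def test_matches_h_inf_and_anchor(self, wt_ssi_cell):
        """Fully equilibrated noiseless conditioning: availability equals the
        inactivation steady state (within 1%), and the most hyperpolarized
        conditioning level is maximal."""
        p = wt_ssi_cell.truth
        df, fit = ssi_curve(wt_ssi_cell)
        np.testing.assert_allclose(
            df["availability"], p.h_inf(df["v"].to_numpy()), atol=0.01
        )
        assert df.loc[df.v == -100.0, "availability"].item() == pytest.approx(1.0, abs=0.01)
        assert fit.converged
        assert fit.v50 == pytest.approx(p.v50_inact, abs=0.1)

    def test_wrong_protocol_rejected(self, wt_iv_cell):
        with pytest.raises(ValueError, match="ssi"):
            ssi_curve(wt_iv_cell)


class TestFitSingleExponential:
    def test_noiseless_decay_exact(self):
        t = np.arange(0, 3000.0, 1.0)
        y = -10.0 * np.exp(-t / 316.0)
        fit = fit_single_exponential(t, y)
        assert fit.converged
        assert fit.tau == pytest.approx(316.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(-10.0, abs=1e-6)

    def test_simulated_slow_inactivation(self, wt_slow_inact_cell):
        fit = inactivation_tau(wt_slow_inact_cell)
        assert fit.converged
        assert fit.tau == pytest.approx(wt_slow_inact_cell.truth.tau_inact, rel=0.02)

    def test_constant_trace_not_converged(self):
        t = np.arange(100.0)
        fit = fit_single_exponential(t, np.full(100, -7.0))
        assert not fit.converged

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_single_exponential(np.arange(4.0), np.arange(4.0))

    def test_tail_deactivation_recovers_tau(self):
        """Tail current at -80 mV decays with the deactivation time constant."""
        cell = noiseless_sweepset("wt", "tail")
        fit = deactivation_tau(cell, -80.0)
        assert fit.converged
        assert fit.tau == pytest.approx(cell.truth.tau_deact, rel=0.05)


class TestPipelineIdentity:
    """Noiseless end-to-end: analysis(simulate(params)) returns the
    generating parameters within 0.1 mV (V50s) and 1 ms (tau)."""

    @pytest.mark.parametrize("preset", ["wt", "v1686m"])
    def test_v50_activation(self, preset):
        cell = noiseless_sweepset(preset, "iv")
        act = activation_curve(build_iv(cell), cell.truth.vrev)
        fit = fit_boltzmann(act["v"], act["g_norm"], "activation")
        assert fit.converged
        assert fit.v50 == pytest.approx(cell.truth.v50_act, abs=0.1)
        assert fit.k == pytest.approx(cell.truth.k_act, abs=0.1)

    @pytest.mark.parametrize("preset", ["wt", "v1686m"])
    def test_v50_inactivation(self, preset):
        cell = noiseless_sweepset(preset, "ssi")
        _, fit = ssi_curve(cell)
        assert fit.v50 == pytest.approx(cell.truth.v50_inact, abs=0.1)

    @pytest.mark.parametrize("preset", ["wt", "v1686m"])
    def test_tau_inactivation(self, preset):
        cell = noiseless_sweepset(preset, "slow_inact")
        fit = inactivation_tau(cell)
        assert fit.tau == pytest.approx(cell.truth.tau_inact, abs=1.0)

    def test_analyze_cell_iv_record(self, wt_iv_cell):
        rec = analyze_cell(wt_iv_cell)
        assert rec["converged"]
        assert rec["peak_density"] == pytest.approx(-21.8, abs=1e-3)
        assert rec["vrev"] == pytest.approx(40.0, abs=1.0)
        assert np.isnan(rec["v50_inact"])
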