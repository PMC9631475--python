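import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvadloop import metrics as mx
from lvadloop.model import Waveforms


def _wave(signals: dict, n=1000):
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    sig = {k: np.broadcast_to(np.asarray(v, float), (n,)).copy() for k, v in signals.items()}
    return Waveforms(time=t, signals=sig, steps_per_cycle=n, n_cycles=1, hr=60.0)


class TestRegurgitantFraction:
    def test_no_backflow_gives_zero(self):
        assert mx.regurgitant_fraction(0.5, 5.0) == 0.0
        assert mx.regurgitant_fraction(0.0, 5.0) == 0.0

    def test_undefined_for_nonpositive_pump_flow(self):
        with pytest.raises(ValueError):
            mx.regurgitant_fraction(-1.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-10.0, 0.0), st.floats(0.1, 10.0))
    def test_definition(self, qao, qlvad):
        assert mx.regurgitant_fraction(qao, qlvad) == pytest.approx(-qao / qlvad)


class TestRegurgitantVolume:
    def test_constant_backflow_integral(self):
        # constant -55.5 ml/s at HR 60 -> -55.5 ml per beat
        q = np.full(800, -55.5)
        assert mx.regurgitant_volume(q, 60.0) == pytest.approx(-55.5, rel=1e-9)

    def test_forward_intervals_excluded(self):
        n = 1000
        q = np.where(np.arange(n) < 100, 50.0, -60.0)
        v = mx.regurgitant_volume(q, 60.0)
        assert v == pytest.approx(-60.0 * 0.9, rel=1e-9)
        # backward-only integral exceeds the net volume in magnitude
        net = np.mean(q) * 1.0
        assert abs(v) >= abs(net)

    def test_trapezoid_matches_dense_riemann(self):
        t = np.linspace(0.0, 1.0, 2000, endpoint=False)
        q = -50.0 + 80.0 * np.sin(2 * np.pi * t)
        ours = mx.regurgitant_volume(q, 60.0)
        td = np.linspace(0.0, 1.0, 200000, endpoint=False)
        dense = np.sum(np.minimum(-50.0 + 80.0 * np.sin(2 * np.pi * td), 0.0)) / 200000
        assert ours == pytest.approx(dense, rel=1e-3)


class TestMeanFlowsAndPressures:
    def test_net_flow_identity(self):
        wf = _wave({"q_ao": -55.5, "q_lvad": 90.3})
        qao, qlvad, net = mx.mean_flows(wf)
        assert qao == pytest.approx(-3.33, abs=0.01)
        assert qlvad == pytest.approx(5.42, abs=0.01)
        assert net == pytest.approx(qao + qlvad)

    def test_no_ai_net_equals_pump_flow(self):
        wf = _wave({"q_ao": 0.0, "q_lvad": 90.0})
        qao, qlvad, net = mx.mean_flows(wf)
        assert qao == 0.0 and net == qlvad

    def test_constant_pressure_statistics(self):
        wf = _wave({"p_sa": 85.0, "p_pa": 22.0, "p_lv": 20.0})
        p = mx.pressures(wf)
        assert p["psa"] == p["psa_max"] == p["psa_min"] == 85.0
        assert p["ppa"] == p["ppa_max"] == p["ppa_min"] == 22.0
        assert p["dp_aov"] == pytest.approx(65.0)


class TestCannulaMetrics:
    def test_constant_flow(self):
        q = np.full(1000, 77.0)
        m = mx.cannula_velocity_metrics(q, 1.54, lv_onset=0.17, lv_duration=0.35, cycle_length=1.0)
        assert m.sd_ratio == pytest.approx(1.0)
        assert m.diastolic_acceleration == pytest.approx(0.0, abs=1e-9)

    def test_linear_ramp_slope_recovered(self):
        """Velocity ramping linearly through diastole: the fitted slope is
        the analytic one."""
        n = 1000
        area = 2.0
        t = np.arange(n) / n
        q = np.where(t < 0.35, 100.0, 100.0 + 40.0 * (t - 0.35))  # ml/s
        m = mx.cannula_velocity_metrics(q, area, lv_onset=0.0, lv_duration=0.35, cycle_length=1.0)
        assert m.diastolic_acceleration == pytest.approx(40.0 / area, rel=0.02)

    def test_nonpositive_end_diastolic_velocity_flagged_not_raised(self):
        q = np.full(1000, -10.0)
        m = mx.cannula_velocity_metrics(q, 1.54, 0.17, 0.35, 1.0)
        assert math.isnan(m.sd_ratio)

    def test_rejects_bad_area(self):
        with pytest.raises(ValueError):
            mx.cannula_velocity_metrics(np.ones(10), 0.0, 0.17, 0.35, 1.0)


class TestBeatMetricsInvariants:
    def _kwargs(self):
        return dict(
            ees_rv=0.364, ea_rv=0.477, ees_over_ea=0.763, sw_rv=851.0,
            mvo2_rv=0.0447, pe_rv=726.0, pva_rv=1577.0, eff_rv=0.127,
            psa=92.0, psa_max=97.0, psa_min=88.0, ppa=24.0, ppa_max=28.0,
            ppa_min=19.0, dp_aov=57.0, qao=-3.33, qlvad=5.42, v_back=-59.0,
            net_flow=2.09, rf=0.613,
        )

    def test_accepts_consistent_row(self):
        m = mx.BeatMetrics(**self._kwargs())
        assert m.pva_rv == m.sw_rv + m.pe_rv

    @pytest.mark.parametrize(
        "patch",
        [dict(pva_rv=1600.0), dict(psa=100.0), dict(ppa=30.0), dict(rf=1.2)],
    )
    def test_rejects_inconsistent_rows(self, patch):
        kw = {**self._kwargs(), **patch}
        with pytest.raises(ValueError):
            mx.BeatMetrics(**kw)
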