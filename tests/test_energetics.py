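import numpy as np
import pytest

from lvadloop import energetics as en


def rectangle_loop(p_lo=10.0, p_hi=20.0, v_lo=50.0, v_hi=60.0, n=50):
    """Rectangular PV loop traversed in the normal orientation."""
    p = np.concatenate([
        np.linspace(p_lo, p_hi, n),          # isovolumic contraction at v_hi
        np.full(n, p_hi),                    # ejection v_hi -> v_lo
        np.linspace(p_hi, p_lo, n),          # isovolumic relaxation at v_lo
        np.full(n, p_lo),                    # filling v_lo -> v_hi
    ])
    v = np.concatenate([
        np.full(n, v_hi),
        np.linspace(v_hi, v_lo, n),
        np.full(n, v_lo),
        np.linspace(v_lo, v_hi, n),
    ])
    return p, v


class TestStrokeWork:
    def test_rectangle_area(self):
        p, v = rectangle_loop()
        assert en.stroke_work(p, v) == pytest.approx(100.0, rel=1e-9)

    def test_shoelace_equals_trapezoid_quadrature(self):
        """Two independent quadratures of the same smooth loop agree."""
        t = np.linspace(0.0, 2 * np.pi, 400, endpoint=False)
        p = 15.0 + 10.0 * np.sin(t)
        v = 55.0 + 8.0 * np.cos(t)
        shoelace = en.stroke_work(p, v)
        trapz = -np.trapezoid(
            np.append(p, p[0]), np.append(v, v[0])
        )  # -oint P dV, trapezoid rule
        assert shoelace == pytest.approx(trapz, rel=1e-3)
        # analytic area of the ellipse: pi * a * b
        assert shoelace == pytest.approx(np.pi * 10.0 * 8.0, rel=1e-3)

    def test_open_trajectory_rejected(self):
        p = np.linspace(0.0, 20.0, 30)
        v = np.linspace(50.0, 80.0, 30)
        with pytest.raises(ValueError):
            en.stroke_work(p, v)


class TestElastanceEstimates:
    def test_ees_recovers_known_emax_on_synthetic_chamber(self):
        """A synthetic elastance chamber with E_max 0.364 is recovered from
        its P(t), V(t) trajectory (grid oracle, within 2%)."""
        e_max, e_min, v0 = 0.364, 0.05, 20.0
        t = np.linspace(0.0, 1.0, 2000, endpoint=False)
        act = np.sin(np.pi * np.clip(t, 0, 0.35) / 0.35) ** 2 * (t < 0.35)
        e = e_min + (e_max - e_min) * act
        v = 120.0 - 40.0 * act  # any positive volume trajectory above v0
        p = e * (v - v0)
        est = en.end_systolic_elastance(p, v, v0)
        assert est == pytest.approx(e_max, rel=0.02)
        # brute-force grid oracle is the same maximum
        assert est == pytest.approx(np.max(p / (v - v0)), rel=1e-12)

    def test_ees_linear_in_emax(self):
        t = np.linspace(0.0, 1.0, 500, endpoint=False)
        act = np.sin(np.pi * t) ** 2
        v = 100.0 + 0.0 * t
        p1 = (0.05 + 0.3 * act) * (v - 10.0)
        p2 = 2.0 * p1
        assert en.end_systolic_elastance(p2, v, 10.0) == pytest.approx(
            2.0 * en.end_systolic_elastance(p1, v, 10.0)
        )

    def test_ees_rejects_subzero_operating_volume(self):
        with pytest.raises(ValueError):
            en.end_systolic_elastance(np.ones(5), np.full(5, 9.0), 10.0)

    def test_arterial_elastance_definition(self):
        # P_es 16.7 mmHg over SV 35 ml -> 0.477 mmHg/ml
        assert en.arterial_elastance(16.7, 35.0) == pytest.approx(0.477, abs=0.001)
        assert en.arterial_elastance(16.7, 70.0) == pytest.approx(0.477 / 2, abs=0.001)
        with pytest.raises(ValueError):
            en.arterial_elastance(16.7, 0.0)


class TestEnergyChain:
    def test_potential_energy_triangle(self):
        # end-systolic P 20 mmHg at V - V0 = 50 ml -> 500 mmHg.ml
        assert en.potential_energy(20.0, 60.0, 10.0) == pytest.approx(500.0)

    def test_mvo2_linear_form(self):
        k = en.EnergeticsConstants(alpha=2e-5, beta=0.01)
        assert en.mvo2(0.0, k) == pytest.approx(0.01)
        assert en.mvo2(1000.0, k) == pytest.approx(0.03)
        with pytest.raises(ValueError):
            en.mvo2(-1.0, k)

    def test_efficiency_formula(self):
        k = en.EnergeticsConstants(alpha=2e-5, beta=0.01)
        # SW in J over MVO2 in J
        assert en.efficiency(851.0, 0.0447, k) == pytest.approx(
            851.0 * k.c_mech / (0.0447 * k.c_o2), rel=1e-12
        )
        assert en.efficiency(0.0, 0.05, k) == 0.0
        with pytest.raises(ValueError):
            en.efficiency(100.0, 0.0, k)

    def test_fit_recovers_exact_linear_data(self):
        rng = np.random.default_rng(7)
        pva = rng.uniform(1000.0, 2500.0, 12)
        m = 2.11e-5 * pva + 1.13e-2
        k = en.fit_mvo2_constants(pva, m)
        assert k.alpha == pytest.approx(2.11e-5, rel=1e-9)
        assert k.beta == pytest.approx(1.13e-2, rel=1e-9)

    def test_constants_must_be_positive(self):
        with pytest.raises(ValueError):
            en.EnergeticsConstants(alpha=-1e-5, beta=0.01)
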