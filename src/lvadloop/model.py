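"""Closed-loop circulation model: assembly, integration, waveforms.

Topology (fixed):

    LA -mitral-> LV -aortic-> SA -R-> SV -R-> RA -tricuspid-> RV
                    \\-pump--/                     -pulmonic-> PA -R-> PV -R-> LA

State vector (17 entries, units mmHg/ml/s/degrees):

    y[0:8]   volumes: V_la, V_lv, V_ra, V_rv, V_sa, V_sv, V_pa, V_pv
    y[8:16]  valve angles/velocities: (theta, omega) for mitral, aortic,
             tricuspid, pulmonic
    y[16]    pump flow Q_lvad

Integration is fixed-step RK4 with post-step projection of the valve angles
onto [theta_min, theta_max]; volume conservation is exact (the volume
equations form a linear invariant of the RHS, which RK4 preserves to
round-off).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import valves as _valves
from .elastance import elastance_at
from .parameters import (
    CHAMBER_KEYS,
    COMPARTMENT_KEYS,
    VALVE_KEYS,
    ParameterSet,
)

__all__ = [
    "CirculationModel",
    "SimulationResults",
    "Waveforms",
    "IntegrationError",
    "PeriodicityWarning",
    "check_periodicity",
    "initial_state",
]

_DEG = math.pi / 180.0

#: default solver settings
DEFAULT_DT = 1.0e-3  # s
DEFAULT_N_CYCLES = 10
PERIODICITY_TOL = 1.0e-3
#: unrecorded equilibration before the recorded cycles (coarse step)
DEFAULT_BURN_IN = 30
BURN_IN_DT = 2.0e-3  # s


class IntegrationError(RuntimeError):
    """Solver divergence or non-finite state during integration."""


class PeriodicityWarning(UserWarning):
    """Simulation ended before the periodic regime was reached."""


# ---------------------------------------------------------------------------
# compiled parameter tuples (pure-float access inside the RHS hot loop)
# ---------------------------------------------------------------------------

def _compile(params: ParameterSet):
    ch = [params.chambers[k] for k in CHAMBER_KEYS]
    chambers = tuple((c.e_max, c.e_min, c.v0, c.onset, c.duration) for c in ch)
    vv = [params.valves[k] for k in VALVE_KEYS]
    valvest = tuple(
        (
            v.theta_min,
            v.theta_max,
            v.k_p,
            v.k_f,
            # precomputed flow gain: Q = gain * frac(theta) * sqrt(|dP|)
            1.0 / math.sqrt(v.b_open),
            1.0 / (1.0 - math.cos(v.theta_max * _DEG)) ** 2,
        )
        for v in vv
    )
    co = [params.compartments[k] for k in COMPARTMENT_KEYS]
    comps = tuple((c.r, c.c, c.v0) for c in co)
    p = params.pump
    pump = (p.a, p.b, p.c, p.r_c, p.l_c, p.speed_rpm)
    return chambers, valvest, comps, pump, 60.0 / params.hr


def _rhs(t: float, y, cp):
    """Time derivative of the state; pure-Python floats for speed."""
    chambers, valvest, comps, pump, T = cp
    sin, cos = math.sin, math.cos

    phase = (t / T) % 1.0
    # chamber pressures P = E(t) (V - V0)
    press = []
    for i in range(4):
        e_max, e_min, v0, onset, dur = chambers[i]
        phi = (phase - onset) % 1.0
        if phi < dur:
            s = sin(math.pi * phi / dur)
            e = e_min + (e_max - e_min) * s * s
        else:
            e = e_min
        press.append(e * (y[i] - v0))
    p_la, p_lv, p_ra, p_rv = press

    (r_sa, _, v0_sa), (r_sv, _, v0_sv), (r_pa, _, v0_pa), (r_pv, _, v0_pv) = comps
    p_sa = (y[4] - v0_sa) / comps[0][1]
    p_sv = (y[5] - v0_sv) / comps[1][1]
    p_pa = (y[6] - v0_pa) / comps[2][1]
    p_pv = (y[7] - v0_pv) / comps[3][1]

    # valve flows + angle dynamics
    dps = (p_la - p_lv, p_lv - p_sa, p_ra - p_rv, p_rv - p_pa)
    q_v = []
    dang = []
    for i in range(4):
        th_min, th_max, k_p, k_f, gain, inv_den = valvest[i]
        th = y[8 + 2 * i]
        om = y[9 + 2 * i]
        dp = dps[i]
        if th < th_min:
            th = th_min
        elif th > th_max:
            th = th_max
        frac = (1.0 - cos(th * _DEG)) ** 2 * inv_den
        if dp >= 0.0:
            q = gain * frac * math.sqrt(dp)
        else:
            q = -gain * frac * math.sqrt(-dp)
        q_v.append(q)
        acc = k_p * dp * cos(th * _DEG) - k_f * om
        if th >= th_max and acc > 0.0:
            acc = 0.0
        elif th <= th_min and acc < 0.0:
            acc = 0.0
        dang.append(om)
        dang.append(acc)
    q_mi, q_ao, q_tri, q_pu = q_v

    # vascular inter-compartment flows
    q_sys = (p_sa - p_sv) / r_sa
    q_sv = (p_sv - p_ra) / r_sv
    q_pa = (p_pa - p_pv) / r_pa
    q_pv = (p_pv - p_la) / r_pv

    # pump branch
    a, b, c, r_c, l_c, rpm = pump
    q_p = y[16]
    head = a * rpm * rpm - b * q_p * abs(q_p) - c * rpm * q_p
    dq_p = (p_lv - p_sa + head - r_c * q_p) / l_c

    return [
        q_pv - q_mi,            # V_la
        q_mi - q_ao - q_p,      # V_lv
        q_sv - q_tri,           # V_ra
        q_tri - q_pu,           # V_rv
        q_ao + q_p - q_sys,     # V_sa
        q_sys - q_sv,           # V_sv
        q_pu - q_pa,            # V_pa
        q_pa - q_pv,            # V_pv
        dang[0], dang[1], dang[2], dang[3],
        dang[4], dang[5], dang[6], dang[7],
        dq_p,
    ]


def _integrate(cp, y0, t0: float, n_steps: int, dt: float) -> np.ndarray:
    """Fixed-step RK4 with valve-angle projection; returns (n_steps+1, 17)."""
    n = len(y0)
    out = np.empty((n_steps + 1, n))
    y = list(map(float, y0))
    out[0] = y
    valvest = cp[1]
    rng = range(n)
    h2 = dt / 2.0
    h6 = dt / 6.0
    for step in range(n_steps):
        t = t0 + step * dt
        k1 = _rhs(t, y, cp)
        y2 = [y[i] + h2 * k1[i] for i in rng]
        k2 = _rhs(t + h2, y2, cp)
        y3 = [y[i] + h2 * k2[i] for i in rng]
        k3 = _rhs(t + h2, y3, cp)
        y4 = [y[i] + dt * k3[i] for i in rng]
        k4 = _rhs(t + dt, y4, cp)
        y = [
            y[i] + h6 * (k1[i] + 2.0 * (k2[i] + k3[i]) + k4[i])
            for i in rng
        ]
        # project valve angles back into their admissible interval
        for i in range(4):
            th_min, th_max = valvest[i][0], valvest[i][1]
            j = 8 + 2 * i
            if y[j] < th_min:
                y[j] = th_min
                if y[j + 1] < 0.0:
                    y[j + 1] = 0.0
            elif y[j] > th_max:
                y[j] = th_max
                if y[j + 1] > 0.0:
                    y[j + 1] = 0.0
        out[step + 1] = y
        if not math.isfinite(y[1]) or not math.isfinite(y[16]):
            raise IntegrationError(
                f"non-finite state at t = {t + dt:.4f} s (step {step + 1}); "
                "check parameter magnitudes and time step"
            )
    return out


#: nominal mean pressures (mmHg) used to shape the initial volume
#: distribution; chambers are taken at their diastolic compliance 1/e_min
_INIT_PRESSURES = {
    "la": 8.0, "lv": 10.0, "ra": 5.0, "rv": 8.0,
    "sa": 85.0, "sv": 8.0, "pa": 22.0, "pv": 10.0,
}


def initial_state(params: ParameterSet) -> np.ndarray:
    """Initial conditions at ventricular diastole.

    Stressed volume is distributed over the nodes in proportion to
    compliance times a nominal physiological pressure profile (scaled so the
    volumes sum to the total blood volume); this lands close enough to the
    periodic regime that all catalogued scenarios converge within 10 cycles.
    Valves start at their minimum angle, the pump at its algebraic
    equilibrium flow for the initial pressures.
    """
    from .pump import pump_equilibrium_flow

    w = [
        _INIT_PRESSURES[k] / params.chambers[k].e_min for k in CHAMBER_KEYS
    ]
    w += [
        _INIT_PRESSURES[k] * params.compartments[k].c for k in COMPARTMENT_KEYS
    ]
    v0 = [params.chambers[k].v0 for k in CHAMBER_KEYS]
    v0 += [params.compartments[k].v0 for k in COMPARTMENT_KEYS]
    stressed = params.total_volume - sum(v0)
    wsum = sum(w)
    vols = [v0[i] + stressed * w[i] / wsum for i in range(8)]

    y = np.zeros(17)
    y[:8] = vols
    for i, k in enumerate(VALVE_KEYS):
        y[8 + 2 * i] = params.valves[k].theta_min
    p_lv = params.chambers["lv"].e_min * (vols[1] - params.chambers["lv"].v0)
    p_sa = (vols[4] - params.compartments["sa"].v0) / params.compartments["sa"].c
    y[16] = pump_equilibrium_flow(p_lv, p_sa, params.pump.speed_rpm, params.pump)
    return y


# ---------------------------------------------------------------------------
# waveform container
# ---------------------------------------------------------------------------

@dataclass
class Waveforms:
    """Time series of all model signals on a shared uniform grid.

    ``signals`` maps names (``p_lv``, ``v_rv``, ``q_ao``, ``q_lvad``,
    ``theta_aortic`` ...) to arrays congruent with ``time``.
    """

    time: np.ndarray
    signals: dict[str, np.ndarray]
    steps_per_cycle: int
    n_cycles: int
    hr: float

    def __post_init__(self) -> None:
        n = self.time.shape[0]
        bad = [k for k, v in self.signals.items() if v.shape[0] != n]
        if bad:
            raise ValueError(f"signals not congruent with time grid: {bad}")

    def cycle(self, k: int) -> "Waveforms":
        """Waveform slice of cycle ``k`` (0-based), endpoint excluded."""
        if not 0 <= k < self.n_cycles:
            raise IndexError(f"cycle {k} outside 0..{self.n_cycles - 1}")
        sl = slice(k * self.steps_per_cycle, (k + 1) * self.steps_per_cycle)
        return Waveforms(
            time=self.time[sl],
            signals={n: v[sl] for n, v in self.signals.items()},
            steps_per_cycle=self.steps_per_cycle,
            n_cycles=1,
            hr=self.hr,
        )

    def last_cycle(self) -> "Waveforms":
        return self.cycle(self.n_cycles - 1)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signals[name]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self, tidy: bool = True) -> pd.DataFrame:
        """Tidy (time, signal, value) frame, or wide frame if tidy=False."""
        wide = pd.DataFrame({"time": self.time, **self.signals})
        if not tidy:
            return wide
        return wide.melt(id_vars="time", var_name="signal", value_name="value")

    def to_csv(self, path, tidy: bool = True) -> None:
        self.to_frame(tidy=tidy).to_csv(path, index=False)


def check_periodicity(cycle_a: Waveforms, cycle_b: Waveforms) -> float:
    """Normalized RMS distance between two cycles; 0 for identical cycles.

    Per signal: RMS(b - a) / RMS(a), with a small floor on the denominator so
    identically-quiescent signals contribute zero rather than 0/0.  The
    reported residual is the max over signals.
    """
    if cycle_a.time.shape != cycle_b.time.shape or set(cycle_a.signals) != set(
        cycle_b.signals
    ):
        raise ValueError("cycles must share grid length and signal set")
    worst = 0.0
    for name, xa in cycle_a.signals.items():
        xb = cycle_b.signals[name]
        diff = math.sqrt(float(np.mean((xb - xa) ** 2)))
        if diff == 0.0:
            continue
        denom = math.sqrt(float(np.mean(xa**2)))
        denom = max(denom, 1e-6)
        worst = max(worst, diff / denom)
    return worst


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class CirculationModel:
    """Closed-loop lumped-parameter circulation with a continuous-flow LVAD.

    Parameters
    ----------
    params : ParameterSet
        Virtual patient plus device setting.

    Examples
    --------
    >>> from lvadloop.scenarios import default_catalogue
    >>> model = CirculationModel(default_catalogue().build("coupled_none_baseline"))
    >>> res = model.simulate()
    >>> round(res.metrics.net_flow, 1)
    5.4
    """

    def __init__(self, params: ParameterSet):
        self.params = params

    @classmethod
    def from_yaml(cls, path) -> "CirculationModel":
        return cls(ParameterSet.from_yaml(path))

    @classmethod
    def from_scenario(cls, scenario: str, catalogue=None) -> "CirculationModel":
        """Build the model for a named catalogue scenario."""
        if catalogue is None:
            from .scenarios import default_catalogue

            catalogue = default_catalogue()
        return cls(catalogue.build(scenario))

    # -- spec surface ---------------------------------------------------
    def system_derivatives(self, t: float, state) -> np.ndarray:
        """d(state)/dt of the assembled system (see module docstring for the
        state layout).  The eight volume derivatives sum to zero exactly:
        the loop is closed, so volume only moves between nodes."""
        state = np.asarray(state, dtype=float)
        if state.shape != (17,):
            raise ValueError(f"state must have shape (17,), got {state.shape}")
        if not np.all(np.isfinite(state)):
            raise IntegrationError(f"non-finite state passed at t={t}: {state}")
        return np.array(_rhs(float(t), list(map(float, state)), _compile(self.params)))

    def simulate(
        self,
        n_cycles: int = DEFAULT_N_CYCLES,
        dt: float = DEFAULT_DT,
        init_state: Optional[np.ndarray] = None,
        periodicity_tol: float = PERIODICITY_TOL,
        burn_in_cycles: int = DEFAULT_BURN_IN,
    ) -> "SimulationResults":
        """Integrate ``n_cycles`` cardiac cycles and return the results.

        When no ``init_state`` is given, the static volume distribution is
        first equilibrated by ``burn_in_cycles`` unrecorded cycles at a
        coarse step (the circulation has a slow venous volume-redistribution
        mode of several seconds that no static initializer can anticipate
        for every scenario).  The recorded run then reaches the periodic
        regime (last-cycle residual below ``periodicity_tol``) within the
        default 10 cycles for every catalogued scenario; a warning is raised
        otherwise.
        """
        if n_cycles < 2:
            raise ValueError("need n_cycles >= 2 to assess periodicity")
        if dt <= 0:
            raise ValueError("dt must be > 0")
        cp = _compile(self.params)
        T = cp[4]
        spc = max(2, round(T / dt))
        dt_eff = T / spc
        if init_state is None:
            y0 = initial_state(self.params)
            if burn_in_cycles > 0:
                spc_b = max(2, round(T / BURN_IN_DT))
                y0 = _integrate(cp, y0, 0.0, spc_b * burn_in_cycles, T / spc_b)[-1]
        else:
            y0 = np.asarray(init_state, float)
        Y = _integrate(cp, y0, 0.0, spc * n_cycles, dt_eff)
        time = np.arange(Y.shape[0]) * dt_eff
        wf = self._waveforms(time, Y, spc, n_cycles)
        residuals = [
            check_periodicity(wf.cycle(k), wf.cycle(k + 1)) for k in range(n_cycles - 1)
        ]
        if residuals[-1] > periodicity_tol:
            warnings.warn(
                f"periodic regime not reached in {n_cycles} cycles "
                f"(residual {residuals[-1]:.2e} > {periodicity_tol:.0e})",
                PeriodicityWarning,
                stacklevel=2,
            )
        return SimulationResults(
            params=self.params,
            waveforms=wf,
            periodicity_residuals=residuals,
            final_state=Y[-1].copy(),
            dt=dt_eff,
        )

    # -- internal -------------------------------------------------------
    def _waveforms(self, time, Y, spc, n_cycles) -> Waveforms:
        p = self.params
        T = p.cycle_length
        sig: dict[str, np.ndarray] = {}
        tc = np.mod(time, T)
        for i, k in enumerate(CHAMBER_KEYS):
            ch = p.chambers[k]
            e = elastance_at(ch, tc, T)
            sig[f"v_{k}"] = Y[:, i]
            sig[f"p_{k}"] = e * (Y[:, i] - ch.v0)
        for i, k in enumerate(COMPARTMENT_KEYS):
            c = p.compartments[k]
            sig[f"v_{k}"] = Y[:, 4 + i]
            sig[f"p_{k}"] = (Y[:, 4 + i] - c.v0) / c.c
        dps = {
            "mitral": sig["p_la"] - sig["p_lv"],
            "aortic": sig["p_lv"] - sig["p_sa"],
            "tricuspid": sig["p_ra"] - sig["p_rv"],
            "pulmonic": sig["p_rv"] - sig["p_pa"],
        }
        for i, k in enumerate(VALVE_KEYS):
            th = Y[:, 8 + 2 * i]
            sig[f"theta_{k}"] = th
            sig[f"q_{k}"] = _valves.valve_flow(dps[k], th, p.valves[k])
        sig["q_ao"] = sig["q_aortic"]
        sig["q_lvad"] = Y[:, 16]
        sig["q_sys"] = (sig["p_sa"] - sig["p_sv"]) / p.compartments["sa"].r
        sig["q_pul"] = (sig["p_pa"] - sig["p_pv"]) / p.compartments["pa"].r
        sig["v_total"] = Y[:, :8].sum(axis=1)
        return Waveforms(
            time=time, signals=sig, steps_per_cycle=spc, n_cycles=n_cycles, hr=p.hr
        )


@dataclass
class SimulationResults:
    """Results of a closed-loop run: waveforms, diagnostics and per-beat
    metrics of the final (periodic) cycle."""

    params: ParameterSet
    waveforms: Waveforms
    periodicity_residuals: list[float]
    final_state: np.ndarray
    dt: float
    _metrics: object = field(default=None, repr=False)

    @property
    def periodicity_residual(self) -> float:
        """Residual between the two final cycles."""
        return self.periodicity_residuals[-1]

    @property
    def volume_drift(self) -> float:
        """|total volume at end - at start| in ml (0 up to round-off)."""
        v = self.waveforms["v_total"]
        return float(abs(v[-1] - v[0]))

    @property
    def metrics(self):
        """BeatMetrics of the final cycle (lazily computed)."""
        if self._metrics is None:
            from .metrics import compute_beat_metrics

            self._metrics = compute_beat_metrics(self.waveforms, self.params)
        return self._metrics

    def summary(self) -> str:
        """Table-style text summary of the final periodic beat."""
        m = self.metrics
        rows = m.to_series()
        lines = [
            "Closed-loop LVAD circulation - final beat summary",
            "=" * 49,
            f"{'HR (bpm)':28s} {self.params.hr:10.0f}",
            f"{'pump speed (RPM)':28s} {self.params.pump.speed_rpm:10.0f}",
            f"{'periodicity residual':28s} {self.periodicity_residual:10.2e}",
            f"{'volume drift (ml)':28s} {self.volume_drift:10.2e}",
            "-" * 49,
        ]
        for name, val in rows.items():
            lines.append(f"{name:28s} {val:10.4g}")
        return "\n".join(lines)

    def plot(self, which: str = "overview"):
        """Quick-look plot: 'overview' (pressures + flows) or 'pv' (RV loop)."""
        import matplotlib.pyplot as plt

        wf = self.waveforms
        if which == "pv":
            fig, ax = plt.subplots()
            last = wf.last_cycle()
            ax.plot(last["v_rv"], last["p_rv"], label="RV")
            ax.plot(last["v_lv"], last["p_lv"], label="LV")
            ax.set_xlabel("volume (ml)")
            ax.set_ylabel("pressure (mmHg)")
            ax.legend()
            return fig
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
        for name in ("p_sa", "p_lv", "p_pa", "p_rv"):
            axes[0].plot(wf.time, wf[name], label=name)
        axes[0].set_ylabel("pressure (mmHg)")
        axes[0].legend(ncol=4, fontsize=8)
        for name in ("q_lvad", "q_ao"):
            axes[1].plot(wf.time, wf[name], label=name)
        axes[1].set_ylabel("flow (ml/s)")
        axes[1].set_xlabel("time (s)")
        axes[1].legend()
        return fig
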