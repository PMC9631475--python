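"""Per-beat hemodynamic and energetic metrics of the final periodic cycle.

Sign conventions follow the reporting tables: retrograde aortic-valve flow
(regurgitation) is negative, the per-beat backward volume ``v_back`` is
negative, the regurgitant fraction is a positive fraction of pump flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

from . import energetics as en
from .elastance import elastance_at
from .model import Waveforms
from .parameters import ParameterSet

__all__ = [
    "BeatMetrics",
    "CannulaMetrics",
    "compute_beat_metrics",
    "mean_flows",
    "regurgitant_fraction",
    "regurgitant_volume",
    "pressures",
    "cannula_velocity_metrics",
]

_ML_S_TO_L_MIN = 60.0 / 1000.0

#: diastolic window for the acceleration slope, as fractions of the
#: diastolic interval measured from end-systole: mid-diastole to just before
#: the next ventricular activation (isovolumic transition excluded).
DIASTOLIC_WINDOW = (0.5, 0.98)


@dataclass(frozen=True)
class CannulaMetrics:
    """Outflow-cannula velocity surrogates of AI severity.

    s_velocity / d_velocity in cm/s; ``sd_ratio`` is peak-systolic over
    end-diastolic velocity (NaN when the end-diastolic velocity is not
    positive); ``diastolic_acceleration`` is the least-squares slope of the
    cannula velocity over the diastolic window, cm/s^2.
    """

    s_velocity: float
    d_velocity: float
    sd_ratio: float
    diastolic_acceleration: float


@dataclass(frozen=True)
class BeatMetrics:
    """One reporting-table column: RV energetics, pressures, flows and
    regurgitation indices of the final periodic beat."""

    ees_rv: float  # mmHg/ml
    ea_rv: float  # mmHg/ml
    ees_over_ea: float  # -
    sw_rv: float  # mmHg.ml
    mvo2_rv: float  # mlO2
    pe_rv: float  # mmHg.ml
    pva_rv: float  # mmHg.ml
    eff_rv: float  # -
    psa: float  # mmHg
    psa_max: float
    psa_min: float
    ppa: float
    ppa_max: float
    ppa_min: float
    dp_aov: float  # mmHg
    qao: float  # L/min, signed (retrograde negative)
    qlvad: float  # L/min
    v_back: float  # ml per beat, signed
    net_flow: float  # L/min
    rf: float  # fraction in [0, 1]
    sd_ratio: float = math.nan
    diastolic_acceleration: float = math.nan

    def __post_init__(self) -> None:
        if abs(self.pva_rv - (self.sw_rv + self.pe_rv)) > 1e-9 * max(1.0, self.pva_rv):
            raise ValueError("PVA must equal SW + PE")
        if not (self.psa_min <= self.psa <= self.psa_max):
            raise ValueError("systemic pressure mean outside [min, max]")
        if not (self.ppa_min <= self.ppa <= self.ppa_max):
            raise ValueError("pulmonary pressure mean outside [min, max]")
        if not 0.0 <= self.rf <= 1.0:
            raise ValueError(f"regurgitant fraction outside [0, 1]: {self.rf}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())


# ---------------------------------------------------------------------------
# flow metrics
# ---------------------------------------------------------------------------

def mean_flows(wf: Waveforms) -> tuple[float, float, float]:
    """(Qao, Qlvad, net flow) in L/min, means over the final beat.

    Net flow = Qlvad + Qao; retrograde aortic-valve flow makes Qao negative.
    """
    last = wf.last_cycle()
    qao = float(np.mean(last["q_ao"])) * _ML_S_TO_L_MIN
    qlvad = float(np.mean(last["q_lvad"])) * _ML_S_TO_L_MIN
    return qao, qlvad, qlvad + qao


def regurgitant_fraction(qao: float, qlvad: float) -> float:
    """RF = max(0, -Qao) / Qlvad, both in consistent flow units."""
    if qlvad <= 0.0:
        raise ValueError(f"regurgitant fraction undefined for Qlvad <= 0 ({qlvad})")
    return max(0.0, -qao) / qlvad


def regurgitant_volume(q_av: np.ndarray, hr: float, dt: Optional[float] = None) -> float:
    """Per-beat backward volume Vback = int min(q_av, 0) dt over one beat, ml.

    ``q_av`` is the aortic-valve flow waveform (ml/s) of one cycle on a
    uniform grid; negative by convention when the valve regurgitates.
    """
    q = np.asarray(q_av, dtype=float)
    if dt is None:
        dt = (60.0 / hr) / q.size
    return float(np.sum(np.minimum(q, 0.0)) * dt)


def pressures(wf: Waveforms) -> dict[str, float]:
    """Systemic/pulmonary arterial pressure statistics and the mean
    transvalvular aortic gradient DPAoV = mean(P_sa - P_lv), all mmHg."""
    last = wf.last_cycle()
    psa, ppa = last["p_sa"], last["p_pa"]
    return {
        "psa": float(np.mean(psa)),
        "psa_max": float(np.max(psa)),
        "psa_min": float(np.min(psa)),
        "ppa": float(np.mean(ppa)),
        "ppa_max": float(np.max(ppa)),
        "ppa_min": float(np.min(ppa)),
        "dp_aov": float(np.mean(last["p_sa"] - last["p_lv"])),
    }


def cannula_velocity_metrics(
    q_lvad: np.ndarray,
    area: float,
    lv_onset: float,
    lv_duration: float,
    cycle_length: float,
) -> CannulaMetrics:
    """Echo-surrogate cannula velocity metrics from one cycle of pump flow.

    The cycle is rolled so that index 0 coincides with ventricular activation
    onset; systole is then the activation window and diastole the remainder.
    S = peak systolic velocity, D = end-diastolic velocity (last sample before
    the next activation).  The diastolic acceleration is the least-squares
    slope of velocity over ``DIASTOLIC_WINDOW`` of the diastolic interval.
    """
    if area <= 0.0:
        raise ValueError("cannula area must be positive")
    q = np.asarray(q_lvad, dtype=float)
    n = q.size
    shift = int(round(lv_onset * n)) % n
    v = np.roll(q, -shift) / area  # cm/s
    n_sys = max(1, int(round(lv_duration * n)))
    s_vel = float(np.max(v[:n_sys]))
    d_vel = float(v[-1])
    sd = s_vel / d_vel if d_vel > 0.0 else math.nan
    lo = n_sys + int(DIASTOLIC_WINDOW[0] * (n - n_sys))
    hi = n_sys + int(DIASTOLIC_WINDOW[1] * (n - n_sys))
    t = np.arange(lo, hi) * (cycle_length / n)
    slope = float(np.polyfit(t, v[lo:hi], 1)[0])
    return CannulaMetrics(
        s_velocity=s_vel, d_velocity=d_vel, sd_ratio=sd, diastolic_acceleration=slope
    )


# ---------------------------------------------------------------------------
# full metric assembly
# ---------------------------------------------------------------------------

def compute_beat_metrics(
    wf: Waveforms,
    params: ParameterSet,
    constants: Optional[en.EnergeticsConstants] = None,
) -> BeatMetrics:
    """Assemble the full BeatMetrics row from the final cycle of ``wf``.

    End-systole is the instant of peak RV elastance (unambiguous in an
    elastance model); Ea uses the RV pressure at that instant over the total
    stroke volume.
    """
    if constants is None:
        constants = en.default_constants()
    last = wf.last_cycle()
    T = params.cycle_length
    rv = params.chambers["rv"]

    qao, qlvad, net = mean_flows(wf)
    rf = regurgitant_fraction(qao, qlvad)
    v_back = regurgitant_volume(last["q_ao"], params.hr, dt=wf.dt)
    pres = pressures(wf)

    p_rv, v_rv = last["p_rv"], last["v_rv"]
    ees = en.end_systolic_elastance(p_rv, v_rv, rv.v0)
    tc = np.mod(last.time, T)
    e_t = elastance_at(rv, tc, T)
    i_es = int(np.argmax(e_t))
    p_es, v_es = float(p_rv[i_es]), float(v_rv[i_es])
    sv = float(np.ptp(v_rv))
    ea = en.arterial_elastance(p_es, sv)
    sw = en.stroke_work(p_rv, v_rv)
    pe = en.potential_energy(p_es, v_es, rv.v0)
    pva = sw + pe
    m = en.mvo2(pva, constants)
    eff = en.efficiency(sw, m, constants)

    lv = params.chambers["lv"]
    cann = cannula_velocity_metrics(
        last["q_lvad"], params.pump.cannula_area, lv.onset, lv.duration, T
    )

    return BeatMetrics(
        ees_rv=ees,
        ea_rv=ea,
        ees_over_ea=ees / ea,
        sw_rv=sw,
        mvo2_rv=m,
        pe_rv=pe,
        pva_rv=pva,
        eff_rv=eff,
        **pres,
        qao=qao,
        qlvad=qlvad,
        v_back=v_back,
        net_flow=net,
        rf=rf,
        sd_ratio=cann.sd_ratio,
        diastolic_acceleration=cann.diastolic_acceleration,
    )
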