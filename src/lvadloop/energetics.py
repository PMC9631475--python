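"""Pressure-volume-loop energetics of a time-varying elastance chamber.

Quantities follow the classical PV-loop framework: stroke work SW is the
loop area, potential energy PE the triangular end-systolic area between the
ESPVR and the volume axis, PVA = SW + PE, myocardial oxygen consumption is
linear in PVA (MVO2 = alpha * PVA + beta), and mechanical efficiency is the
stroke work expressed in Joules divided by the energy equivalent of the
oxygen consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnergeticsConstants",
    "default_constants",
    "fit_mvo2_constants",
    "stroke_work",
    "end_systolic_elastance",
    "arterial_elastance",
    "potential_energy",
    "mvo2",
    "efficiency",
]

#: J per mmHg.ml (1 mmHg.ml = 1.33322e-4 J)
C_MECH = 1.33322e-4
#: J per ml O2 (caloric equivalent of oxygen)
C_O2 = 20.0


@dataclass(frozen=True)
class EnergeticsConstants:
    """Constants of the PVA -> MVO2 -> efficiency chain.

    alpha : mlO2 per mmHg.ml, slope of the linear PVA-MVO2 relation
    beta  : mlO2, its intercept (basal + activation metabolism per beat)
    c_mech: J per mmHg.ml, work unit conversion
    c_o2  : J per mlO2, caloric equivalent of oxygen
    """

    alpha: float
    beta: float
    c_mech: float = C_MECH
    c_o2: float = C_O2

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.c_mech, self.c_o2) <= 0.0:
            raise ValueError("all energetics constants must be positive")


def fit_mvo2_constants(pva, mvo2_values) -> EnergeticsConstants:
    """Least-squares (alpha, beta) of MVO2 = alpha * PVA + beta."""
    pva = np.asarray(pva, dtype=float)
    m = np.asarray(mvo2_values, dtype=float)
    if pva.shape != m.shape or pva.size < 2:
        raise ValueError("need >= 2 matching (PVA, MVO2) pairs")
    A = np.column_stack([pva, np.ones_like(pva)])
    (alpha, beta), *_ = np.linalg.lstsq(A, m, rcond=None)
    return EnergeticsConstants(alpha=float(alpha), beta=float(beta))


def default_constants() -> EnergeticsConstants:
    """Constants frozen at calibration time: least-squares fit over the
    (PVA, MVO2) pairs of the packaged reference tables."""
    from .reporting import reference_table

    ref = reference_table()
    pairs = ref[["pva_rv", "mvo2_rv"]].drop_duplicates()
    return fit_mvo2_constants(pairs["pva_rv"], pairs["mvo2_rv"])


def stroke_work(pressure, volume, closure_tol: float = 0.05) -> float:
    """Loop area -oint P dV (mmHg.ml) of a closed PV trajectory.

    Positive for the normal orientation (ejection at high pressure).  The
    loop must be closed: the first and last points may differ by at most
    ``closure_tol`` of the loop's pressure/volume span (the trajectory of a
    periodic beat qualifies; the closing segment is appended automatically).
    """
    p = np.asarray(pressure, dtype=float)
    v = np.asarray(volume, dtype=float)
    if p.shape != v.shape or p.size < 3:
        raise ValueError("pressure and volume must be matching arrays of >= 3 points")
    p_span = max(np.ptp(p), 1e-12)
    v_span = max(np.ptp(v), 1e-12)
    if abs(p[-1] - p[0]) > closure_tol * p_span or abs(v[-1] - v[0]) > closure_tol * v_span:
        raise ValueError("PV trajectory is not closed (non-periodic beat)")
    p = np.append(p, p[0])
    v = np.append(v, v[0])
    # shoelace in the (V, P) plane; normal loops run counterclockwise there
    area = 0.5 * float(np.sum(v[:-1] * p[1:] - v[1:] * p[:-1]))
    return area


def end_systolic_elastance(pressure, volume, v0: float) -> float:
    """Ees (mmHg/ml) as the beat maximum of P / (V - V0).

    For a pure elastance chamber this recovers the configured peak elastance
    exactly (up to grid resolution).
    """
    p = np.asarray(pressure, dtype=float)
    v = np.asarray(volume, dtype=float)
    if np.any(v <= v0):
        raise ValueError("volume at or below V0 encountered; Ees undefined")
    return float(np.max(p / (v - v0)))


def arterial_elastance(p_es: float, stroke_volume: float) -> float:
    """Effective arterial elastance Ea = P_es / SV (mmHg/ml)."""
    if stroke_volume <= 0.0:
        raise ValueError("stroke volume must be positive")
    return p_es / stroke_volume


def potential_energy(p_es: float, v_es: float, v0: float) -> float:
    """Triangular end-systolic potential energy PE = P_es (V_es - V0) / 2."""
    return 0.5 * p_es * (v_es - v0)


def mvo2(pva: float, k: EnergeticsConstants) -> float:
    """Oxygen consumption per beat (mlO2): MVO2 = alpha * PVA + beta."""
    if pva < 0.0:
        raise ValueError(f"PVA must be >= 0, got {pva}")
    return k.alpha * pva + k.beta


def efficiency(sw: float, mvo2_value: float, k: EnergeticsConstants) -> float:
    """Mechanical efficiency: (SW in J) / (MVO2 in J)."""
    if mvo2_value <= 0.0:
        raise ValueError(f"MVO2 must be > 0, got {mvo2_value}")
    return (sw * k.c_mech) / (mvo2_value * k.c_o2)
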