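"""Continuous-flow pump element (centrifugal, HeartMate-3-like).

The pump sits between the LV apex and the ascending aorta (the systemic
arterial node).  Its pressure head follows a standard centrifugal H-Q
characteristic, quadratic in rotor speed and strictly decreasing in forward
flow; the cannula adds a series resistance and inertance so the pump flow is
a state variable:

    L_c dQ/dt = P_lv - P_ao + H(Q, w) - R_c Q
"""

from __future__ import annotations

from .parameters import PumpParams

__all__ = ["pump_head", "pump_flow_derivative", "pump_equilibrium_flow"]


def pump_head(q: float, rpm: float, params: PumpParams) -> float:
    """Pressure head H (mmHg) at flow q (ml/s) and rotor speed rpm.

    H(q, w) = a*w^2 - b*q*|q| - c*w*q: shut-off head a*w^2 at zero flow,
    monotonically decreasing in forward flow, non-positive for q > 0 at
    zero speed.
    """
    return params.a * rpm * rpm - params.b * q * abs(q) - params.c * rpm * q


def pump_flow_derivative(
    q: float, p_lv: float, p_ao: float, rpm: float, params: PumpParams
) -> float:
    """dQ/dt (ml/s^2) of the cannula-pump branch."""
    return (p_lv - p_ao + pump_head(q, rpm, params) - params.r_c * q) / params.l_c


def pump_equilibrium_flow(
    p_lv: float, p_ao: float, rpm: float, params: PumpParams, tol: float = 1e-10
) -> float:
    """Algebraic steady-state flow: solves H(Q, w) + P_lv - P_ao = R_c Q.

    Used as the zero-inertance fallback and as an independent check of the
    dynamic branch; bisection on the strictly decreasing residual.
    """
    def resid(q: float) -> float:
        return p_lv - p_ao + pump_head(q, rpm, params) - params.r_c * q

    lo, hi = -2000.0, 2000.0
    if resid(lo) < 0.0 or resid(hi) > 0.0:
        raise ValueError("pump equilibrium flow outside bracket [-2000, 2000] ml/s")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
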