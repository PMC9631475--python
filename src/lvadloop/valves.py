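"""Dynamic heart-valve model: opening-angle dynamics, effective orifice area
and the turbulent (quadratic) pressure-flow law.

The leaflet angle theta obeys a second-order ODE driven by the transvalvular
pressure difference (Korakianitis-Shi family):

    d2theta/dt2 = k_p * dP * cos(theta) - k_f * dtheta/dt

clamped to [theta_min, theta_max].  Aortic insufficiency is imposed purely by
raising theta_min above zero so the valve retains a residual orifice when
"closed"; a perfect valve has theta_min = 0.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .parameters import ValveParams

__all__ = [
    "valve_angle_dynamics",
    "effective_area",
    "area_fraction",
    "valve_flow",
    "valve_flow_derivative",
]

logger = logging.getLogger(__name__)

_DEG = math.pi / 180.0


def valve_angle_dynamics(theta: float, omega: float, dp: float, params: ValveParams) -> float:
    """Angular acceleration (deg/s^2) of the leaflet.

    Forward pressure (dp > 0) drives the valve open, reverse pressure drives
    it toward theta_min.  At either bound the outward component of motion is
    suppressed so the state never leaves [theta_min, theta_max].
    """
    theta = min(max(theta, params.theta_min), params.theta_max)
    acc = params.k_p * dp * math.cos(theta * _DEG) - params.k_f * omega
    if theta >= params.theta_max and acc > 0.0:
        acc = 0.0
    if theta <= params.theta_min and acc < 0.0:
        acc = 0.0
    return acc


def area_fraction(theta, params: ValveParams):
    """Fractional effective orifice area in (0, 1], the (1-cos)^2 mapping.

    frac(theta) = (1 - cos theta)^2 / (1 - cos theta_max)^2 — smooth,
    strictly increasing, zero only at theta = 0.
    """
    th = np.clip(np.asarray(theta, dtype=float), params.theta_min, params.theta_max)
    num = 1.0 - np.cos(th * _DEG)
    den = 1.0 - math.cos(params.theta_max * _DEG)
    frac = (num / den) ** 2
    if frac.ndim == 0:
        return float(frac)
    return frac


def effective_area(theta, params: ValveParams):
    """Effective orifice area (cm^2) at leaflet angle theta (degrees)."""
    th = np.asarray(theta, dtype=float)
    if np.any(th < params.theta_min - 1e-9) or np.any(th > params.theta_max + 1e-9):
        logger.debug(
            "valve angle %s outside [%s, %s]; clamping",
            theta, params.theta_min, params.theta_max,
        )
    return params.a_max * area_fraction(theta, params)


def valve_flow(dp, theta, params: ValveParams):
    """Quasi-steady flow (ml/s) through the valve under the turbulent law.

    dP = B(theta) * Q * |Q| with B(theta) = b_open / frac(theta)^2, i.e.
    Q = sign(dP) * frac(theta) * sqrt(|dP| / b_open).  A fully closed valve
    (zero area) carries no flow regardless of dP.
    """
    frac = area_fraction(theta, params)
    q = np.sign(dp) * frac * np.sqrt(np.abs(np.asarray(dp, dtype=float)) / params.b_open)
    if np.ndim(q) == 0:
        return float(q)
    return q


def valve_flow_derivative(q: float, dp: float, theta: float, params: ValveParams) -> float:
    """dQ/dt (ml/s^2) when the valve has nonzero flow inertance.

    L_v dQ/dt = dP - B(theta) * Q * |Q|.  Only used if ``params.l_v > 0``;
    the assembled loop defaults to the algebraic law above.
    """
    if params.l_v <= 0.0:
        raise ValueError("valve_flow_derivative requires l_v > 0; use valve_flow")
    frac = area_fraction(theta, params)
    if frac <= 0.0:
        return -q / max(params.l_v, 1e-12)  # closed valve: flow decays
    b_theta = params.b_open / frac**2
    return (dp - b_theta * q * abs(q)) / params.l_v
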