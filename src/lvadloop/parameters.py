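"""Parameter containers for the closed-loop circulation model.

Internal unit system: mmHg, ml, s (degrees for valve angles, RPM for pump
speed).  Flows are therefore ml/s and are only converted to L/min at the
reporting boundary.

A :class:`ParameterSet` fully describes one virtual patient plus device
setting: the four cardiac chambers (time-varying elastance), the four heart
valves (opening-angle dynamics with a turbulent pressure-flow law), four
windkessel vascular compartments (systemic/pulmonary, arterial/venous), the
continuous-flow pump bridging LV apex and ascending aorta, heart rate and
total blood volume.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ChamberParams",
    "VascularCompartment",
    "ValveParams",
    "PumpParams",
    "ParameterSet",
    "CHAMBER_KEYS",
    "VALVE_KEYS",
    "COMPARTMENT_KEYS",
]

#: canonical ordering used throughout the state vector assembly
CHAMBER_KEYS = ("la", "lv", "ra", "rv")
VALVE_KEYS = ("mitral", "aortic", "tricuspid", "pulmonic")
COMPARTMENT_KEYS = ("sa", "sv", "pa", "pv")

# 0.5 * rho / (conversion dyn/cm^2 -> mmHg), with rho = 1.06 g/ml.  Gives the
# Bernoulli-type loss coefficient B = _RHO_HALF_MMHG / A^2 in mmHg.s^2/ml^2
# for an orifice of area A cm^2.
_RHO_HALF_MMHG = 1.06 / (2.0 * 1333.22)


class InvalidParameterError(ValueError):
    """Raised when a parameter container violates its physical invariants."""


@dataclass
class ChamberParams:
    """Time-varying elastance chamber.

    Pressure is ``P = E(t) * (V - v0)`` with ``E(t)`` sweeping between
    ``e_min`` (diastole) and ``e_max`` (peak systole) following a squared-sine
    activation starting at fraction ``onset`` of the cycle and lasting
    fraction ``duration``.
    """

    e_max: float  # mmHg/ml
    e_min: float  # mmHg/ml
    v0: float  # ml, unstressed volume
    onset: float = 0.0  # fraction of cycle
    duration: float = 0.35  # fraction of cycle

    def __post_init__(self) -> None:
        if not (self.e_max >= self.e_min > 0.0):
            raise InvalidParameterError(
                f"need e_max >= e_min > 0, got e_max={self.e_max}, e_min={self.e_min}"
            )
        if self.v0 < 0.0:
            raise InvalidParameterError(f"unstressed volume must be >= 0, got {self.v0}")
        if not 0.0 <= self.onset < 1.0:
            raise InvalidParameterError(f"onset must be in [0, 1), got {self.onset}")
        if not 0.0 < self.duration <= 1.0:
            raise InvalidParameterError(f"duration must be in (0, 1], got {self.duration}")


@dataclass
class VascularCompartment:
    """Windkessel compartment: compliance chamber draining through a resistance.

    ``r`` is the resistance of the outflow path toward the next compartment
    downstream; ``l`` is an optional inertance (0 disables it).
    """

    r: float  # mmHg.s/ml
    c: float  # ml/mmHg
    v0: float  # ml
    l: float = 0.0  # mmHg.s^2/ml

    def __post_init__(self) -> None:
        if self.r <= 0.0:
            raise InvalidParameterError(f"resistance must be > 0, got {self.r}")
        if self.c <= 0.0:
            raise InvalidParameterError(f"compliance must be > 0, got {self.c}")
        if self.l < 0.0:
            raise InvalidParameterError(f"inertance must be >= 0, got {self.l}")
        if self.v0 < 0.0:
            raise InvalidParameterError(f"unstressed volume must be >= 0, got {self.v0}")


@dataclass
class ValveParams:
    """Heart valve with second-order opening-angle dynamics.

    The leaflet angle lives in ``[theta_min, theta_max]`` degrees; a perfectly
    competent valve has ``theta_min = 0`` (zero residual orifice).  Raising
    ``theta_min`` of the aortic valve is how aortic insufficiency is imposed:
    the valve can no longer close below that angle, leaving a permanent
    regurgitant orifice.

    The pressure-flow law across the open valve is turbulent (quadratic):
    ``dP = B(theta) * Q * |Q|`` with ``B(theta) = b_open / frac(theta)**2``
    where ``frac`` is the fractional effective area.  ``b_open`` defaults to
    the Bernoulli loss coefficient of the full-open orifice ``a_max``.
    """

    a_max: float  # cm^2, effective orifice area at theta_max
    theta_min: float = 0.0  # degrees
    theta_max: float = 75.0  # degrees
    k_p: float = 3.2e5  # deg/(s^2.mmHg), pressure coupling of the angle ODE
    k_f: float = 50.0  # 1/s, angular damping
    b_open: float | None = None  # mmHg.s^2/ml^2, loss coefficient at full open
    l_v: float = 0.0  # mmHg.s^2/ml, flow inertance (0 -> algebraic flow)

    def __post_init__(self) -> None:
        if self.a_max <= 0.0:
            raise InvalidParameterError(f"a_max must be > 0, got {self.a_max}")
        if not 0.0 <= self.theta_min < self.theta_max <= 90.0:
            raise InvalidParameterError(
                f"need 0 <= theta_min < theta_max <= 90, got "
                f"theta_min={self.theta_min}, theta_max={self.theta_max}"
            )
        if self.b_open is None:
            self.b_open = _RHO_HALF_MMHG / self.a_max**2
        if self.b_open <= 0.0:
            raise InvalidParameterError(f"b_open must be > 0, got {self.b_open}")
        if self.k_p <= 0.0 or self.k_f < 0.0:
            raise InvalidParameterError("angle dynamics coefficients must be positive")
        if self.l_v < 0.0:
            raise InvalidParameterError(f"valve inertance must be >= 0, got {self.l_v}")


@dataclass
class PumpParams:
    """Continuous-flow pump (HeartMate-3-like centrifugal device).

    Head characteristic ``H(Q, w) = a*w^2 - b*Q*|Q| - c*w*Q`` (mmHg, with Q
    in ml/s and w in RPM): quadratic shut-off head in speed, strictly
    decreasing in forward flow.  The cannula contributes a series resistance
    ``r_c`` and inertance ``l_c``; ``cannula_area`` converts flow to the
    outflow-graft velocity used by the echo-surrogate metrics.
    """

    speed_rpm: float
    a: float  # mmHg/RPM^2
    b: float  # mmHg.s^2/ml^2
    c: float  # mmHg.s/(RPM.ml)
    r_c: float = 0.035  # mmHg.s/ml
    l_c: float = 0.02  # mmHg.s^2/ml
    cannula_area: float = 1.54  # cm^2 (14 mm outflow graft)

    def __post_init__(self) -> None:
        if self.speed_rpm < 0.0:
            raise InvalidParameterError(f"pump speed must be >= 0, got {self.speed_rpm}")
        if self.a <= 0.0 or self.b <= 0.0 or self.c < 0.0:
            raise InvalidParameterError(
                "pump characteristic needs a > 0, b > 0, c >= 0 "
                f"(got a={self.a}, b={self.b}, c={self.c})"
            )
        if self.r_c <= 0.0 or self.l_c <= 0.0:
            raise InvalidParameterError("cannula r_c and l_c must be > 0")
        if self.cannula_area <= 0.0:
            raise InvalidParameterError("cannula area must be > 0")


@dataclass
class ParameterSet:
    """One virtual patient plus device setting.

    The closed loop is fixed by construction:

    ``LA -mitral-> LV -{aortic, pump}-> SA -> SV -> RA -tricuspid-> RV
    -pulmonic-> PA -> PV -> LA``

    so every node has exactly one upstream and one downstream path (the LV
    having the aortic valve and the pump in parallel toward SA), and total
    blood volume is conserved by the flow bookkeeping.
    """

    chambers: dict[str, ChamberParams]
    valves: dict[str, ValveParams]
    compartments: dict[str, VascularCompartment]
    pump: PumpParams
    hr: float  # beats/min
    total_volume: float  # ml
    tags: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in CHAMBER_KEYS if k not in self.chambers]
        missing += [k for k in VALVE_KEYS if k not in self.valves]
        missing += [k for k in COMPARTMENT_KEYS if k not in self.compartments]
        if missing:
            raise InvalidParameterError(f"missing model elements: {missing}")
        if self.hr <= 0.0:
            raise InvalidParameterError(f"heart rate must be > 0, got {self.hr}")
        if self.total_volume <= 0.0:
            raise InvalidParameterError(
                f"total blood volume must be > 0, got {self.total_volume}"
            )
        v0_sum = sum(c.v0 for c in self.chambers.values()) + sum(
            c.v0 for c in self.compartments.values()
        )
        if self.total_volume <= v0_sum:
            raise InvalidParameterError(
                f"total volume {self.total_volume} ml does not exceed the summed "
                f"unstressed volume {v0_sum} ml; the loop would have no stressed volume"
            )

    # -- convenience ----------------------------------------------------
    @property
    def cycle_length(self) -> float:
        """Cardiac cycle length in seconds."""
        return 60.0 / self.hr

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            chambers={k: ChamberParams(**v) for k, v in d["chambers"].items()},
            valves={k: ValveParams(**v) for k, v in d["valves"].items()},
            compartments={
                k: VascularCompartment(**v) for k, v in d["compartments"].items()
            },
            pump=PumpParams(**d["pump"]),
            hr=float(d["hr"]),
            total_volume=float(d["total_volume"]),
            tags=dict(d.get("tags", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def seed_parameter_set() -> ParameterSet:
    """Textbook starting point for calibration: a chronically supported
    heart-failure circulation on a continuous-flow pump at 5,500 RPM.

    These values are the *seed* of the calibration search, not the shipped
    baseline; see :mod:`lvadloop.calibrate`.  Chamber timing: atrial kick in
    late diastole, ventricular systole occupying ~35% of the cycle.
    """
    chambers = {
        "la": ChamberParams(e_max=0.25, e_min=0.12, v0=10.0, onset=0.03, duration=0.14),
        "lv": ChamberParams(e_max=0.60, e_min=0.06, v0=25.0, onset=0.17, duration=0.35),
        "ra": ChamberParams(e_max=0.20, e_min=0.10, v0=10.0, onset=0.03, duration=0.14),
        "rv": ChamberParams(e_max=0.364, e_min=0.045, v0=20.0, onset=0.17, duration=0.35),
    }
    valves = {
        "mitral": ValveParams(a_max=4.0),
        "aortic": ValveParams(a_max=3.0),
        "tricuspid": ValveParams(a_max=5.0),
        "pulmonic": ValveParams(a_max=3.5),
    }
    compartments = {
        "sa": VascularCompartment(r=0.83, c=1.3, v0=500.0),
        "sv": VascularCompartment(r=0.02, c=60.0, v0=2400.0),
        "pa": VascularCompartment(r=0.14, c=4.0, v0=120.0),
        "pv": VascularCompartment(r=0.025, c=25.0, v0=400.0),
    }
    pump = PumpParams(speed_rpm=5500.0, a=3.0e-6, b=1.8e-3, c=2.0e-6)
    return ParameterSet(
        chambers=chambers,
        valves=valves,
        compartments=compartments,
        pump=pump,
        hr=60.0,
        total_volume=5300.0,
    )
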