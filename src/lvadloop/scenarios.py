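"""Scenario catalogue: phenotype and management transforms on a calibrated
baseline parameter set.

Phenotypes combine the RV-to-pulmonary-artery coupling state with the
severity of aortic insufficiency; management strategies are pure parameter
transforms, exactly as in the underlying in-silico study:

* ``speed_augmentation`` - pump speed 5,500 -> 6,400 RPM
* ``bp_control``         - systemic resistance scaled to 50-60% of baseline
                           (target central MAP 70-75 mmHg)
* ``pulmonary_vasodilation`` - pulmonary compliance x~10, resistance x0.8
                           (defined for the uncoupled phenotypes)
* ``pulm_vasodilation_plus_bp`` - both of the above (they commute: disjoint
                           parameters)

The numeric constants of the catalogue (aortic minimum angles for the two AI
grades, the uncoupling factors, the BP-control factor) are frozen at
calibration time and shipped in ``data/calibrated.yaml``.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass, field
from typing import Iterable, Optional

import yaml

from .parameters import ParameterSet

__all__ = [
    "ScenarioSpec",
    "ScenarioCatalogue",
    "default_catalogue",
    "apply_ai",
    "apply_uncoupling",
    "apply_speed",
    "apply_bp_control",
    "apply_pulmonary_vasodilation",
]

RV_STATES = ("coupled", "uncoupled")
AI_SEVERITIES = ("none", "mild_moderate", "severe")
MANAGEMENTS = (
    "baseline",
    "speed_augmentation",
    "bp_control",
    "pulmonary_vasodilation",
    "pulm_vasodilation_plus_bp",
)

#: severity thresholds on the regurgitant fraction / coupling ratio
RF_SEVERE_THRESHOLD = 0.50
COUPLING_THRESHOLD = 0.70


@dataclass(frozen=True)
class ScenarioSpec:
    """Phenotype (coupling x AI severity) plus management strategy."""

    rv_state: str
    ai_severity: str
    management: str = "baseline"

    def __post_init__(self) -> None:
        if self.rv_state not in RV_STATES:
            raise ValueError(f"rv_state must be one of {RV_STATES}")
        if self.ai_severity not in AI_SEVERITIES:
            raise ValueError(f"ai_severity must be one of {AI_SEVERITIES}")
        if self.management not in MANAGEMENTS:
            raise ValueError(f"management must be one of {MANAGEMENTS}")
        if (
            self.management in ("pulmonary_vasodilation", "pulm_vasodilation_plus_bp")
            and self.rv_state != "uncoupled"
        ):
            raise ValueError("pulmonary vasodilation is defined for uncoupled phenotypes")

    @property
    def name(self) -> str:
        return f"{self.rv_state}_{self.ai_severity}_{self.management}"

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        for rv in RV_STATES:
            for ai in AI_SEVERITIES:
                for mg in MANAGEMENTS:
                    if name == f"{rv}_{ai}_{mg}":
                        return cls(rv, ai, mg)
        raise ValueError(f"unknown scenario name: {name!r}")


def table_specs() -> list[ScenarioSpec]:
    """The 16 scenarios of the reference tables (6 coupled + 10 uncoupled)."""
    specs = []
    for ai in ("severe", "mild_moderate"):
        for mg in ("baseline", "speed_augmentation", "bp_control"):
            specs.append(ScenarioSpec("coupled", ai, mg))
    for ai in ("severe", "mild_moderate"):
        for mg in MANAGEMENTS:
            specs.append(ScenarioSpec("uncoupled", ai, mg))
    return specs


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def apply_ai(
    params: ParameterSet,
    severity: str,
    theta_min_mild: Optional[float] = None,
    theta_min_severe: Optional[float] = None,
    svr_factor_mild: Optional[float] = None,
    svr_factor_severe: Optional[float] = None,
) -> ParameterSet:
    """Impose aortic insufficiency; ``none`` restores a perfect valve.

    The transform has two parts, both frozen at calibration time:

    * the aortic valve's minimum closing angle is raised, leaving a permanent
      regurgitant orifice (severe -> simulated RF > 50%, mild/moderate ->
      RF below 50%);
    * systemic vascular resistance is raised by a severity-dependent factor,
      the chronic vasoconstrictive compensation that maintains arterial
      pressure when net perfusion falls (without it the published AI
      phenotypes - high MAP at low net flow - cannot exist in any model in
      which mean systemic flow equals mean pressure drop over resistance).
    """
    if severity not in AI_SEVERITIES:
        raise ValueError(f"severity must be one of {AI_SEVERITIES}")
    out = params.copy()
    if severity == "none":
        theta, svr = 0.0, 1.0
    else:
        need_cat = (
            theta_min_mild is None
            or theta_min_severe is None
            or svr_factor_mild is None
            or svr_factor_severe is None
        )
        if need_cat:
            cat = default_catalogue()
            theta_min_mild = cat.theta_min_mild if theta_min_mild is None else theta_min_mild
            theta_min_severe = (
                cat.theta_min_severe if theta_min_severe is None else theta_min_severe
            )
            svr_factor_mild = (
                cat.ai_svr_factor_mild if svr_factor_mild is None else svr_factor_mild
            )
            svr_factor_severe = (
                cat.ai_svr_factor_severe if svr_factor_severe is None else svr_factor_severe
            )
        if severity == "severe":
            theta, svr = theta_min_severe, svr_factor_severe
        else:
            theta, svr = theta_min_mild, svr_factor_mild
    out.valves["aortic"].theta_min = float(theta)
    out.compartments["sa"].r *= float(svr)
    out.tags["ai_severity"] = severity
    return out


def apply_uncoupling(
    params: ParameterSet,
    r_factor: Optional[float] = None,
    c_factor: Optional[float] = None,
) -> ParameterSet:
    """RV-PA uncoupling: remodel the pulmonary arterial bed (compliance down,
    resistance up) so the no-AI coupling ratio falls below 0.7.

    RV contractility is left untouched (the phenotype is vascular).  The
    transform is idempotent: an already-uncoupled set is returned unchanged.
    """
    out = params.copy()
    if out.tags.get("rv_state") == "uncoupled":
        return out
    if r_factor is None or c_factor is None:
        cat = default_catalogue()
        r_factor = cat.uncouple_r_factor if r_factor is None else r_factor
        c_factor = cat.uncouple_c_factor if c_factor is None else c_factor
    pa = out.compartments["pa"]
    pa.r *= float(r_factor)
    pa.c *= float(c_factor)
    out.tags["rv_state"] = "uncoupled"
    return out


def apply_speed(params: ParameterSet, rpm: float) -> ParameterSet:
    """Set the pump rotor speed; nothing else changes."""
    if rpm <= 0.0:
        raise ValueError(f"rpm must be > 0, got {rpm}")
    out = params.copy()
    out.pump.speed_rpm = float(rpm)
    return out


def apply_bp_control(params: ParameterSet, factor: Optional[float] = None) -> ParameterSet:
    """Blood-pressure control: systemic vascular resistance scaled to
    50-60% of baseline (calibrated within that band to a 70-75 mmHg MAP)."""
    if factor is None:
        factor = default_catalogue().bp_factor
    if not 0.5 <= factor <= 0.6:
        raise ValueError(f"BP-control factor must lie in [0.5, 0.6], got {factor}")
    out = params.copy()
    out.compartments["sa"].r *= float(factor)
    out.tags["bp_control"] = True
    return out


def apply_pulmonary_vasodilation(
    params: ParameterSet, c_factor: float = 10.0, r_factor: float = 0.8
) -> ParameterSet:
    """Pulmonary vasodilation: pulmonary compliance x ~10, resistance x 0.8
    (targets a systolic PA pressure around 25 mmHg in the uncoupled
    phenotypes)."""
    out = params.copy()
    pa = out.compartments["pa"]
    pa.c *= float(c_factor)
    pa.r *= float(r_factor)
    out.tags["pulmonary_vasodilation"] = True
    return out


# ---------------------------------------------------------------------------
# catalogue
# ---------------------------------------------------------------------------

@dataclass
class ScenarioCatalogue:
    """Calibrated baseline plus the frozen transform constants.

    ``build`` produces the ParameterSet of any scenario by composing the
    transforms on the baseline (coupled, no AI, 5,500 RPM).
    """

    baseline: ParameterSet
    theta_min_mild: float
    theta_min_severe: float
    bp_factor: float
    uncouple_r_factor: float
    uncouple_c_factor: float
    ai_svr_factor_mild: float = 1.0
    ai_svr_factor_severe: float = 1.0
    vasodil_c_factor: float = 10.0
    vasodil_r_factor: float = 0.8
    baseline_rpm: float = 5500.0
    augmented_rpm: float = 6400.0
    meta: dict = field(default_factory=dict)

    def build(self, spec: ScenarioSpec | str) -> ParameterSet:
        if isinstance(spec, str):
            spec = ScenarioSpec.from_name(spec)
        p = self.baseline.copy()
        p.tags["rv_state"] = "coupled"
        if spec.rv_state == "uncoupled":
            p = apply_uncoupling(p, self.uncouple_r_factor, self.uncouple_c_factor)
        p = apply_ai(
            p,
            spec.ai_severity,
            self.theta_min_mild,
            self.theta_min_severe,
            self.ai_svr_factor_mild,
            self.ai_svr_factor_severe,
        )
        if spec.management == "speed_augmentation":
            p = apply_speed(p, self.augmented_rpm)
        elif spec.management == "bp_control":
            p = apply_bp_control(p, self.bp_factor)
        elif spec.management == "pulmonary_vasodilation":
            p = apply_pulmonary_vasodilation(
                p, self.vasodil_c_factor, self.vasodil_r_factor
            )
        elif spec.management == "pulm_vasodilation_plus_bp":
            p = apply_pulmonary_vasodilation(
                p, self.vasodil_c_factor, self.vasodil_r_factor
            )
            p = apply_bp_control(p, self.bp_factor)
        p.tags["scenario"] = spec.name
        return p

    def specs(self, include_no_ai: bool = True) -> list[ScenarioSpec]:
        out = []
        if include_no_ai:
            out += [
                ScenarioSpec("coupled", "none", "baseline"),
                ScenarioSpec("uncoupled", "none", "baseline"),
            ]
        out += table_specs()
        return out

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "theta_min_mild": self.theta_min_mild,
            "theta_min_severe": self.theta_min_severe,
            "bp_factor": self.bp_factor,
            "uncouple_r_factor": self.uncouple_r_factor,
            "uncouple_c_factor": self.uncouple_c_factor,
            "ai_svr_factor_mild": self.ai_svr_factor_mild,
            "ai_svr_factor_severe": self.ai_svr_factor_severe,
            "vasodil_c_factor": self.vasodil_c_factor,
            "vasodil_r_factor": self.vasodil_r_factor,
            "baseline_rpm": self.baseline_rpm,
            "augmented_rpm": self.augmented_rpm,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioCatalogue":
        d = dict(d)
        d["baseline"] = ParameterSet.from_dict(d["baseline"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioCatalogue":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def export_configs(self, directory, specs: Optional[Iterable[ScenarioSpec]] = None):
        """Write one ``<scenario>.yaml`` ParameterSet config per scenario."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for spec in specs if specs is not None else self.specs():
            path = directory / f"{spec.name}.yaml"
            self.build(spec).to_yaml(path)
            written.append(path)
        return written


_DEFAULT_CATALOGUE: Optional[ScenarioCatalogue] = None


def default_catalogue() -> ScenarioCatalogue:
    """The calibrated catalogue shipped with the package (cached)."""
    global _DEFAULT_CATALOGUE
    if _DEFAULT_CATALOGUE is None:
        ref = _resources.files("lvadloop.data").joinpath("calibrated.yaml")
        with _resources.as_file(ref) as path:
            _DEFAULT_CATALOGUE = ScenarioCatalogue.from_yaml(path)
    return _DEFAULT_CATALOGUE
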