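"""Calibration of the virtual patient against printed physiological targets,
sensitivity analysis, and random virtual-patient generation.

The underlying study adjusted its model manually, guided by a +/-40%
sensitivity analysis, until the baseline mimicked standard physiology
(HR 60 bpm, MAP 80-90 mmHg, mean PA pressure 20-25 mmHg at 5,500 RPM) and
the phenotype scenarios matched the reported hemodynamics.  Here the same
adjustment is done by deterministic least squares:

* :func:`calibrate_baseline` fits the coupled no-AI baseline (systemic and
  pulmonary resistance, pump shut-off coefficient, total blood volume, RV
  diastolic stiffness) to the physiological target vector.
* :func:`calibrate_catalogue` then fits the full scenario catalogue - the
  two aortic minimum angles, the pump flow-sensitivity coefficients, the
  BP-control factor and the pulmonary uncoupling factors - against the
  published scenario hemodynamics (net flows, pump/valve flows, coupling
  ratios and the management percent-responses).

Both are deterministic: fixed seeds, fixed evaluation order, fixed solver
settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .energetics import EnergeticsConstants
from .metrics import BeatMetrics, compute_beat_metrics
from .model import CirculationModel, IntegrationError
from .parameters import ParameterSet, seed_parameter_set
from .scenarios import ScenarioCatalogue

__all__ = [
    "BaselineTargets",
    "CalibrationResult",
    "calibrate_baseline",
    "calibrate_catalogue",
    "simulate_metrics",
    "sensitivity_analysis",
    "random_virtual_patient",
]

# interim constants for metric evaluation during calibration; the PVA-MVO2
# chain does not feed back on the flow/pressure targets
_CAL_CONSTANTS = EnergeticsConstants(alpha=2.1e-5, beta=0.0113)


def simulate_metrics(
    params: ParameterSet,
    n_cycles: int = 10,
    dt: float = 1e-3,
    init_state: Optional[np.ndarray] = None,
    constants: Optional[EnergeticsConstants] = None,
) -> tuple[BeatMetrics, np.ndarray]:
    """Run one scenario and return (final-beat metrics, final state)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = CirculationModel(params).simulate(
            n_cycles=n_cycles, dt=dt, init_state=init_state
        )
    m = compute_beat_metrics(
        res.waveforms, params, constants if constants is not None else _CAL_CONSTANTS
    )
    return m, res.final_state


@dataclass(frozen=True)
class BaselineTargets:
    """Physiological targets of the coupled, no-AI baseline at 5,500 RPM."""

    net_flow: float = 5.4  # L/min
    map_mmhg: float = 85.0  # center of the 80-90 band
    mpap_mmhg: float = 22.5  # center of the 20-25 band
    ees_over_ea: float = 1.01


@dataclass
class CalibrationResult:
    """Outcome of a calibration stage."""

    params: ParameterSet
    achieved: dict[str, float]
    targets: dict[str, float]
    residual_norm: float
    n_evaluations: int
    success: bool
    catalogue: Optional[ScenarioCatalogue] = None
    notes: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, tgt in self.targets.items():
            ach = self.achieved.get(k, math.nan)
            rows.append(
                {
                    "target": k,
                    "wanted": tgt,
                    "achieved": ach,
                    "rel_dev": (ach - tgt) / tgt if tgt else math.nan,
                }
            )
        return pd.DataFrame(rows).set_index("target")


# ---------------------------------------------------------------------------
# knob plumbing
# ---------------------------------------------------------------------------

def _knob_map(p: ParameterSet) -> dict[str, tuple[Callable, Callable]]:
    """Accessors for the tunable parameters of a working ParameterSet."""
    return {
        "r_sys": (
            lambda: p.compartments["sa"].r,
            lambda v: setattr(p.compartments["sa"], "r", v),
        ),
        "r_pul": (
            lambda: p.compartments["pa"].r,
            lambda v: setattr(p.compartments["pa"], "r", v),
        ),
        "c_pul": (
            lambda: p.compartments["pa"].c,
            lambda v: setattr(p.compartments["pa"], "c", v),
        ),
        "pump_a": (lambda: p.pump.a, lambda v: setattr(p.pump, "a", v)),
        "pump_b": (lambda: p.pump.b, lambda v: setattr(p.pump, "b", v)),
        "pump_c": (lambda: p.pump.c, lambda v: setattr(p.pump, "c", v)),
        "v_total": (
            lambda: p.total_volume,
            lambda v: setattr(p, "total_volume", v),
        ),
        "rv_e_min": (
            lambda: p.chambers["rv"].e_min,
            lambda v: setattr(p.chambers["rv"], "e_min", v),
        ),
    }


def _apply_x(knobs: Sequence[str], x: np.ndarray, kmap) -> None:
    for name, val in zip(knobs, x):
        kmap[name][1](float(val))


# ---------------------------------------------------------------------------
# stage 1: baseline
# ---------------------------------------------------------------------------

def calibrate_baseline(
    seed: Optional[ParameterSet] = None,
    targets: BaselineTargets = BaselineTargets(),
    max_nfev: int = 60,
    n_cycles: int = 10,
    dt: float = 1e-3,
    verbose: bool = False,
) -> CalibrationResult:
    """Fit the coupled no-AI baseline to the physiological target vector.

    Knobs: systemic resistance, pulmonary resistance, pump shut-off
    coefficient, total blood volume and RV diastolic stiffness (the last
    controls RV operating volume and therefore the Ees/Ea ratio).
    """
    work = (seed if seed is not None else seed_parameter_set()).copy()
    work.valves["aortic"].theta_min = 0.0
    knobs = ["r_sys", "r_pul", "pump_a", "v_total", "rv_e_min"]
    kmap = _knob_map(work)
    x0 = np.array([kmap[k][0]() for k in knobs])
    nev = [0]

    tgt = {
        "net_flow": targets.net_flow,
        "map": targets.map_mmhg,
        "mpap": targets.mpap_mmhg,
        "ees_over_ea": targets.ees_over_ea,
    }

    def resid(x: np.ndarray) -> np.ndarray:
        _apply_x(knobs, x, kmap)
        nev[0] += 1
        try:
            m, _ = simulate_metrics(work, n_cycles=n_cycles, dt=dt)
        except (IntegrationError, ValueError):
            return np.full(4, 10.0)
        r = np.array(
            [
                5.0 * (m.net_flow - tgt["net_flow"]) / tgt["net_flow"],
                1.0 * (m.psa - tgt["map"]) / tgt["map"],
                1.5 * (m.ppa - tgt["mpap"]) / tgt["mpap"],
                3.0 * (m.ees_over_ea - tgt["ees_over_ea"]) / tgt["ees_over_ea"],
            ]
        )
        if verbose:
            print(f"  eval {nev[0]:3d}: |r| = {np.linalg.norm(r):.4f}")
        return r

    sol = least_squares(
        resid,
        x0,
        bounds=(x0 * 0.2, x0 * 5.0),
        diff_step=0.03,
        max_nfev=max_nfev,
        x_scale=x0,
    )
    _apply_x(knobs, sol.x, kmap)
    m, _ = simulate_metrics(work, n_cycles=n_cycles, dt=dt)
    achieved = {
        "net_flow": m.net_flow,
        "map": m.psa,
        "mpap": m.ppa,
        "ees_over_ea": m.ees_over_ea,
    }
    return CalibrationResult(
        params=work.copy(),
        achieved=achieved,
        targets=tgt,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_evaluations=nev[0],
        success=bool(sol.success),
    )


# ---------------------------------------------------------------------------
# stage 2: scenario catalogue
# ---------------------------------------------------------------------------

#: published scenario-level targets (flows L/min, pressures mmHg, ratios
#: dimensionless, responses as ratios to the phenotype baseline)
#: banded targets: no pull inside the stated physiological band, linear
#: penalty outside (the study states bands, not point values, for these)
CATALOGUE_BANDS: dict[str, tuple[float, float]] = {
    "c_none.map": (80.0, 90.0),
    "c_none.mpap": (20.0, 25.0),
    "c_sev_bp.psa": (70.0, 78.0),
}

CATALOGUE_TARGETS: dict[str, float] = {
    "c_none.net_flow": 5.4,
    "c_none.map": 85.0,
    "c_none.mpap": 22.5,
    "c_none.ees_over_ea": 1.01,
    "c_sev.net_flow": 2.10,
    "c_sev.qlvad": 5.42,
    "c_sev.rf": 0.613,
    "c_sev.ees_over_ea": 0.762,
    "c_mild.rf": 0.163,
    "c_mild.net_flow": 4.47,
    "c_sev_speed.net_ratio": 1.42,
    "c_mild_speed.net_ratio": 1.389,
    "c_sev_bp.net_ratio": 1.81,
    "c_sev_bp.psa": 73.0,
    "u_none.net_flow": 5.0,
    "u_none.ees_over_ea": 0.47,
    "u_sev.net_flow": 1.78,
    "u_sev.ees_over_ea": 0.285,
    "u_sev_speed.net_ratio": 1.455,
    "u_sev_comb.net_ratio": 2.13,
}

#: the published Psa cells of the AI phenotypes cannot coexist with the
#: published management responses in a fixed linear systemic bed (see the
#: methods note); the management responses and severity classification get
#: the weight.
_CAT_WEIGHTS: dict[str, float] = {
    "c_none.net_flow": 8.0,
    "c_none.map": 6.0,
    "c_none.mpap": 3.0,
    "c_none.ees_over_ea": 6.0,
    "c_sev.net_flow": 3.0,
    "c_sev.qlvad": 1.5,
    "c_sev.rf": 2.5,
    "c_sev.ees_over_ea": 3.0,
    "c_mild.rf": 2.0,
    "c_mild.net_flow": 1.0,
    "c_sev_speed.net_ratio": 10.0,
    "c_mild_speed.net_ratio": 1.0,
    "c_sev_bp.net_ratio": 20.0,
    "c_sev_bp.psa": 0.3,
    "u_none.net_flow": 5.0,
    "u_none.ees_over_ea": 2.0,
    "u_sev.net_flow": 4.0,
    "u_sev.ees_over_ea": 2.0,
    "u_sev_speed.net_ratio": 1.0,
    "u_sev_comb.net_ratio": 6.0,
}


def _catalogue_measurements(cat: ScenarioCatalogue, n_cycles: int, dt: float) -> dict:
    """Simulate the scenarios the catalogue targets refer to, each cold from
    the equilibrated initializer (the same protocol every downstream
    consumer uses)."""
    out: dict[str, float] = {}
    m0, _ = simulate_metrics(cat.build("coupled_none_baseline"), n_cycles=n_cycles, dt=dt)
    out["c_none.net_flow"] = m0.net_flow
    out["c_none.map"] = m0.psa
    out["c_none.mpap"] = m0.ppa
    out["c_none.ees_over_ea"] = m0.ees_over_ea

    def run(name: str) -> BeatMetrics:
        m, _ = simulate_metrics(cat.build(name), n_cycles=n_cycles, dt=dt)
        return m

    m_sev = run("coupled_severe_baseline")
    out["c_sev.net_flow"] = m_sev.net_flow
    out["c_sev.qlvad"] = m_sev.qlvad
    out["c_sev.rf"] = m_sev.rf
    out["c_sev.ees_over_ea"] = m_sev.ees_over_ea
    m_mild = run("coupled_mild_moderate_baseline")
    out["c_mild.rf"] = m_mild.rf
    out["c_mild.net_flow"] = m_mild.net_flow
    out["c_sev_speed.net_ratio"] = run("coupled_severe_speed_augmentation").net_flow / m_sev.net_flow
    out["c_mild_speed.net_ratio"] = (
        run("coupled_mild_moderate_speed_augmentation").net_flow / m_mild.net_flow
    )
    m_bp = run("coupled_severe_bp_control")
    out["c_sev_bp.net_ratio"] = m_bp.net_flow / m_sev.net_flow
    out["c_sev_bp.psa"] = m_bp.psa
    m_un = run("uncoupled_none_baseline")
    out["u_none.net_flow"] = m_un.net_flow
    out["u_none.ees_over_ea"] = m_un.ees_over_ea
    m_usev = run("uncoupled_severe_baseline")
    out["u_sev.net_flow"] = m_usev.net_flow
    out["u_sev.ees_over_ea"] = m_usev.ees_over_ea
    out["u_sev_speed.net_ratio"] = (
        run("uncoupled_severe_speed_augmentation").net_flow / m_usev.net_flow
    )
    out["u_sev_comb.net_ratio"] = (
        run("uncoupled_severe_pulm_vasodilation_plus_bp").net_flow / m_usev.net_flow
    )
    return out


def calibrate_catalogue(
    baseline: ParameterSet,
    targets: Optional[dict[str, float]] = None,
    max_nfev: int = 400,
    n_cycles: int = 8,
    dt: float = 1e-3,
    verbose: bool = False,
    seed_catalogue: Optional[ScenarioCatalogue] = None,
) -> CalibrationResult:
    """Least-squares fit of the scenario catalogue constants against the
    published scenario hemodynamics (see ``CATALOGUE_TARGETS``).

    The stage-1 baseline knobs stay fixed.  The pump's flow-sensitivity
    coefficients (b, c) are free, but its shut-off coefficient is re-derived
    at every step so the head at the baseline operating point is preserved -
    this decouples the speed-response knobs from the already-calibrated
    baseline and keeps the search well conditioned.
    """
    tgt = dict(CATALOGUE_TARGETS if targets is None else targets)
    work = baseline.copy()
    # baseline pump operating point to preserve
    m0, _ = simulate_metrics(work, n_cycles=10, dt=dt)
    q_ref = m0.qlvad / 0.06  # ml/s
    from .pump import pump_head

    w_ref = work.pump.speed_rpm
    # preserve head net of cannula loss so r_c can move freely
    net_head_ref = pump_head(q_ref, w_ref, work.pump) - work.pump.r_c * q_ref

    # knobs: pump_b, pump_c, cannula r_c, LV e_max, LV e_min, total volume,
    #        RV e_min, systemic venous C, systemic R, theta_sev, theta_mild,
    #        svr_sev, svr_mild, bp_factor, unc_r, unc_c
    lv_e0 = work.chambers["lv"].e_max
    lv_emin0 = work.chambers["lv"].e_min
    vt0 = work.total_volume
    rve0 = work.chambers["rv"].e_min
    svc0 = work.compartments["sv"].c
    rs0 = work.compartments["sa"].r
    if seed_catalogue is not None:
        sb = seed_catalogue.baseline
        head_scale0 = float(seed_catalogue.meta.get("head_scale", 1.0))
        x0 = np.array(
            [sb.pump.b, sb.pump.c, sb.pump.r_c, sb.chambers["lv"].e_max,
             sb.chambers["lv"].e_min, sb.total_volume, sb.chambers["rv"].e_min,
             sb.compartments["sv"].c, sb.compartments["sa"].r,
             seed_catalogue.theta_min_severe, seed_catalogue.theta_min_mild,
             seed_catalogue.ai_svr_factor_severe, seed_catalogue.ai_svr_factor_mild,
             seed_catalogue.bp_factor, seed_catalogue.uncouple_r_factor,
             seed_catalogue.uncouple_c_factor, head_scale0]
        )
    else:
        x0 = np.array(
            [3.0e-4, 0.0, 0.04, lv_e0, lv_emin0, vt0, rve0, svc0, rs0,
             33.0, 23.0, 2.9, 1.2, 0.55, 1.25, 0.11, 1.0]
        )
    lo = np.array(
        [1.0e-4, 0.0, 0.001, 0.12, 0.015, vt0 * 0.80, rve0 * 0.6, 15.0, rs0 * 0.6,
         15.0, 8.0, 1.0, 1.0, 0.50, 1.01, 0.02, 0.75]
    )
    hi = np.array(
        [5.0e-3, 3.0e-4, 0.30, 1.60, 0.12, vt0 * 1.20, rve0 * 1.5, 90.0, rs0 * 1.4,
         55.0, 45.0, 5.0, 3.0, 0.60, 3.00, 0.80, 1.40]
    )
    scale = np.array(
        [2e-4, 5e-5, 0.03, 0.2, 0.02, vt0 * 0.1, rve0 * 0.2, 15.0, rs0 * 0.2,
         8.0, 8.0, 1.0, 0.5, 0.05, 0.3, 0.1, 0.1]
    )
    x0 = np.clip(x0, lo, hi)
    names = sorted(tgt)
    w = np.array([_CAT_WEIGHTS.get(n, 1.0) for n in names])
    nev = [0]

    def make_catalogue(x: np.ndarray) -> ScenarioCatalogue:
        (b, c, r_c, lv_e, lv_emin, v_tot, rv_emin, sv_c, r_sys,
         th_sev, th_mild, svr_sev, svr_mild, bp_f, un_r, un_c,
         head_scale) = (float(v) for v in x)
        work.pump.b = b
        work.pump.c = c
        work.pump.r_c = r_c
        work.chambers["lv"].e_min = lv_emin
        work.chambers["lv"].e_max = max(lv_e, lv_emin)
        work.total_volume = v_tot
        work.chambers["rv"].e_min = min(rv_emin, work.chambers["rv"].e_max)
        work.compartments["sv"].c = sv_c
        work.compartments["sa"].r = r_sys
        # anchor the pump at a (scalable) baseline operating head, net of
        # cannula loss; head_scale shifts the whole characteristic up/down
        work.pump.a = (
            head_scale * net_head_ref
            + r_c * q_ref + b * q_ref * abs(q_ref) + c * w_ref * q_ref
        ) / w_ref**2
        return ScenarioCatalogue(
            baseline=work.copy(),
            theta_min_mild=th_mild,
            theta_min_severe=th_sev,
            bp_factor=bp_f,
            uncouple_r_factor=un_r,
            uncouple_c_factor=un_c,
            ai_svr_factor_mild=svr_mild,
            ai_svr_factor_severe=svr_sev,
            meta={"head_scale": head_scale},
        )

    def one_resid(name: str, value: float) -> float:
        if name in CATALOGUE_BANDS:
            lo_b, hi_b = CATALOGUE_BANDS[name]
            excess = max(lo_b - value, 0.0) + max(value - hi_b, 0.0)
            return excess / tgt[name]
        return (value - tgt[name]) / abs(tgt[name])

    def resid(x: np.ndarray) -> np.ndarray:
        nev[0] += 1
        cat = make_catalogue(x)
        try:
            meas = _catalogue_measurements(cat, n_cycles=n_cycles, dt=dt)
        except (IntegrationError, ValueError):
            return np.full(len(names), 10.0)
        r = w * np.array([one_resid(n, meas[n]) for n in names])
        if verbose:
            print(f"  eval {nev[0]:3d}: |r| = {np.linalg.norm(r):.5f}", flush=True)
        return r

    sol = least_squares(
        resid,
        x0,
        bounds=(lo, hi),
        diff_step=0.03,
        max_nfev=max_nfev,
        x_scale=scale,
    )
    cat = make_catalogue(sol.x)
    achieved = _catalogue_measurements(cat, n_cycles=10, dt=dt)
    return CalibrationResult(
        params=cat.baseline,
        achieved=achieved,
        targets=tgt,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_evaluations=nev[0],
        success=bool(sol.success),
        catalogue=cat,
    )


# ---------------------------------------------------------------------------
# sensitivity analysis and virtual patients
# ---------------------------------------------------------------------------

#: parameters perturbed in the sensitivity analysis
SENSITIVITY_PARAMETERS = (
    "sa.r", "sa.c", "sv.r", "sv.c", "pa.r", "pa.c", "pv.r", "pv.c",
    "lv.e_max", "lv.e_min", "rv.e_max", "rv.e_min",
    "la.e_max", "ra.e_max", "aortic.theta_min",
)

_SENS_OUTPUTS = ("net_flow", "psa", "ppa", "ees_over_ea", "rf")


def _get_path(p: ParameterSet, path: str) -> float:
    node, attr = path.split(".")
    if node in p.compartments:
        return getattr(p.compartments[node], attr)
    if node in p.chambers:
        return getattr(p.chambers[node], attr)
    return getattr(p.valves[node], attr)


def _set_path(p: ParameterSet, path: str, value: float) -> None:
    node, attr = path.split(".")
    if node in p.compartments:
        setattr(p.compartments[node], attr, value)
    elif node in p.chambers:
        setattr(p.chambers[node], attr, value)
    else:
        setattr(p.valves[node], attr, value)


def sensitivity_analysis(
    params: ParameterSet,
    perturbation: float = 0.40,
    parameters: Sequence[str] = SENSITIVITY_PARAMETERS,
    n_cycles: int = 10,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """One-at-a-time +/-``perturbation`` sensitivity of the main outputs.

    Returns a DataFrame indexed by ``parameter`` and ``direction`` (+/-/0)
    whose entries are relative output changes against the unperturbed run;
    a failed perturbed simulation is flagged with NaNs and the sweep
    continues.  theta_min perturbations are skipped when the valve is
    competent (theta_min = 0 has no scale to perturb).
    """
    m_ref, s_ref = simulate_metrics(params, n_cycles=n_cycles, dt=dt)
    ref = {k: getattr(m_ref, k) for k in _SENS_OUTPUTS}
    rows = []
    rows.append({"parameter": "(none)", "direction": "0", **{k: 0.0 for k in _SENS_OUTPUTS}})
    for path in parameters:
        base_val = _get_path(params, path)
        if base_val == 0.0:
            continue
        for sign, label in ((1.0, "+"), (-1.0, "-")):
            p = params.copy()
            _set_path(p, path, base_val * (1.0 + sign * perturbation))
            row = {"parameter": path, "direction": label}
            try:
                m, _ = simulate_metrics(p, n_cycles=n_cycles, dt=dt, init_state=s_ref)
                for k in _SENS_OUTPUTS:
                    denom = ref[k] if abs(ref[k]) > 1e-9 else 1.0
                    row[k] = (getattr(m, k) - ref[k]) / denom
            except (IntegrationError, ValueError):
                row.update({k: math.nan for k in _SENS_OUTPUTS})
                row["direction"] = label + " (failed)"
            rows.append(row)
    return pd.DataFrame(rows).set_index(["parameter", "direction"])


def random_virtual_patient(
    seed: int, baseline: Optional[ParameterSet] = None, spread: float = 0.20
) -> ParameterSet:
    """Reproducible random virtual patient: the calibrated baseline with
    uniform +/-``spread`` perturbations of the vascular and elastance
    parameters."""
    if baseline is None:
        from .scenarios import default_catalogue

        baseline = default_catalogue().baseline
    rng = np.random.default_rng(seed)
    p = baseline.copy()
    for comp in p.compartments.values():
        comp.r *= float(rng.uniform(1 - spread, 1 + spread))
        comp.c *= float(rng.uniform(1 - spread, 1 + spread))
    for ch in p.chambers.values():
        factor = float(rng.uniform(1 - spread, 1 + spread))
        ch.e_max *= factor
        ch.e_min *= float(rng.uniform(1 - spread, 1 + spread))
        if ch.e_min > ch.e_max:
            ch.e_min = ch.e_max
    p.tags["virtual_patient_seed"] = int(seed)
    return p
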