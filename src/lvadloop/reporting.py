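"""Scenario-matrix orchestration, percent-change summaries and comparison
against the packaged reference tables."""

from __future__ import annotations

import importlib.resources as _resources
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .calibrate import simulate_metrics
from .energetics import EnergeticsConstants
from .model import IntegrationError
from .scenarios import ScenarioCatalogue, ScenarioSpec, default_catalogue

__all__ = [
    "reference_table",
    "run_scenario_matrix",
    "percent_changes",
    "compare_to_reference",
    "ComparisonReport",
    "DEFAULT_TOLERANCES",
    "write_matrix",
    "read_matrix",
]

logger = logging.getLogger(__name__)

#: metrics reported on a ratio/fraction scale, compared with absolute bands
_RATIO_METRICS = ("ees_over_ea", "eff_rv", "rf")

#: default tolerance policy: +/-5% relative for flows/pressures/energetics,
#: +/-0.05 absolute for dimensionless ratios
DEFAULT_TOLERANCES = {"relative": 0.05, "ratio_abs": 0.05}

#: columns present in the printed reference tables
TABLE_COLUMNS = [
    "ees_rv", "ea_rv", "ees_over_ea", "sw_rv", "mvo2_rv", "pe_rv", "pva_rv",
    "eff_rv", "psa", "psa_max", "psa_min", "ppa", "ppa_max", "ppa_min",
    "dp_aov", "qao", "qlvad", "v_back", "net_flow", "rf",
]


def reference_table() -> pd.DataFrame:
    """The 16 published scenario columns, indexed by scenario name."""
    ref = _resources.files("lvadloop.data").joinpath("reference_tables.csv")
    with _resources.as_file(ref) as path:
        df = pd.read_csv(path).set_index("scenario")
    return df


def run_scenario_matrix(
    catalogue: Optional[ScenarioCatalogue] = None,
    specs: Optional[Iterable[ScenarioSpec]] = None,
    n_cycles: int = 10,
    dt: float = 1e-3,
    constants: Optional[EnergeticsConstants] = None,
    include_no_ai: bool = True,
) -> pd.DataFrame:
    """Simulate every catalogued scenario; one BeatMetrics row per scenario.

    Deterministic for fixed solver settings.  A scenario whose simulation
    fails is flagged (``ok = False``, metric columns NaN) and the run
    continues.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    if constants is None:
        from .energetics import default_constants

        constants = default_constants()
    if specs is None:
        specs = catalogue.specs(include_no_ai=include_no_ai)
    rows = {}
    for spec in specs:
        try:
            m, _ = simulate_metrics(
                catalogue.build(spec), n_cycles=n_cycles, dt=dt, constants=constants
            )
            rows[spec.name] = {"ok": True, **m.to_dict()}
        except (IntegrationError, ValueError) as exc:  # flag and continue
            logger.warning("scenario %s failed: %s", spec.name, exc)
            rows[spec.name] = {"ok": False}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "scenario"
    return df


def percent_changes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Management responses relative to each phenotype's own baseline.

    For every non-baseline scenario row: percent change in net flow, in
    per-beat regurgitant volume (the prose-style "RF reduction": it tracks
    Vback, not RF points) and in RV MVO2, plus the change of the regurgitant
    fraction in percentage points.
    """
    out = []
    for name in matrix.index:
        spec = ScenarioSpec.from_name(name)
        if spec.management == "baseline":
            continue
        base_name = ScenarioSpec(spec.rv_state, spec.ai_severity, "baseline").name
        if base_name not in matrix.index:
            raise KeyError(f"baseline scenario {base_name!r} missing from matrix")
        row, base = matrix.loc[name], matrix.loc[base_name]
        out.append(
            {
                "scenario": name,
                "baseline": base_name,
                "d_net_flow_pct": 100.0 * (row["net_flow"] / base["net_flow"] - 1.0),
                "d_v_back_pct": 100.0 * (row["v_back"] / base["v_back"] - 1.0)
                if base["v_back"] != 0
                else math.nan,
                "d_mvo2_pct": 100.0 * (row["mvo2_rv"] / base["mvo2_rv"] - 1.0),
                "d_rf_points": 100.0 * (row["rf"] - base["rf"]),
            }
        )
    return pd.DataFrame(out).set_index("scenario")


@dataclass
class ComparisonReport:
    """Per scenario x metric comparison against the reference table."""

    table: pd.DataFrame  # columns: simulated, reference, deviation, tolerance, passed

    @property
    def pass_rate(self) -> float:
        return float(self.table["passed"].mean())

    @property
    def n_failed(self) -> int:
        return int((~self.table["passed"]).sum())

    def failures(self) -> pd.DataFrame:
        return self.table[~self.table["passed"]]

    def summary(self) -> str:
        return (
            f"{int(self.table['passed'].sum())}/{len(self.table)} cells within "
            f"tolerance (pass rate {self.pass_rate:.1%})"
        )


def compare_to_reference(
    matrix: pd.DataFrame,
    reference: Optional[pd.DataFrame] = None,
    tolerances: Optional[dict] = None,
    metrics: Optional[Iterable[str]] = None,
) -> ComparisonReport:
    """Compare a simulated scenario matrix with the reference table.

    Ratio-scale metrics use an absolute band, everything else a relative
    one.  Only scenarios present in both tables are compared.
    """
    if reference is None:
        reference = reference_table()
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    metrics = list(metrics) if metrics is not None else TABLE_COLUMNS
    rows = []
    shared = [s for s in reference.index if s in matrix.index]
    if not shared:
        raise ValueError("no shared scenarios between matrix and reference")
    for scen in shared:
        for met in metrics:
            sim = float(matrix.loc[scen, met])
            ref = float(reference.loc[scen, met])
            if met in _RATIO_METRICS:
                dev = sim - ref
                band = tol["ratio_abs"]
            else:
                dev = (sim - ref) / ref if ref != 0 else math.inf * np.sign(sim or 1)
                band = tol["relative"]
            rows.append(
                {
                    "scenario": scen,
                    "metric": met,
                    "simulated": sim,
                    "reference": ref,
                    "deviation": dev,
                    "tolerance": band,
                    "passed": bool(abs(dev) <= band),
                }
            )
    return ComparisonReport(pd.DataFrame(rows).set_index(["scenario", "metric"]))


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="scenario")
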