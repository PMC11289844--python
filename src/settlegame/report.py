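"""Structured JSON reports and CSV table exports.

All numbers are serialised at 12 significant digits and keys are sorted, so
two runs of the same configuration produce byte-identical payloads.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .config import RunConfig
from .dynamics import (
    BasinScanResult,
    PhaseField,
    Trajectory,
    basin_scan,
    interior_grid,
)
from .equilibria import (
    StabilityRecord,
    classify_scenario,
    corner_stability_table,
    enumerate_equilibria,
    find_ess,
)
from .model import validate_parameters
from .sensitivity import SweepResult, SweepSpec, sweep

__all__ = [
    "run_report",
    "write_report",
    "stability_frame",
    "trajectory_frame",
    "sweep_frame",
    "phase_frame",
]

log = logging.getLogger("settlegame")


def _num(value: float) -> float:
    """Round to 12 significant digits for stable serialisation."""
    return float(f"{float(value):.12g}")


def _point(coords: tuple[float, float] | None) -> list[float] | None:
    return None if coords is None else [_num(coords[0]), _num(coords[1])]


def stability_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    """One row per corner equilibrium: coordinates, Jacobian, det, trace, class."""
    rows = []
    for r in records:
        j = r.jacobian
        rows.append(
            {
                "name": r.point.name,
                "x": r.point.coords[0],
                "y": r.point.coords[1],
                "j11": j[0, 0], "j12": j[0, 1], "j21": j[1, 0], "j22": j[1, 1],
                "det": r.det,
                "trace": r.trace,
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {"t": traj.times, "x": traj.states[:, 0], "y": traj.states[:, 1]}
    )


def sweep_frame(result: SweepResult) -> pd.DataFrame:
    """One row per swept value with ESS, basin limit and scenario index."""
    rows = []
    for r in result.records:
        limit = r.basin_limit
        rows.append(
            {
                "value": r.value,
                "scenario_id": r.scenario.scenario_id,
                "ess": ";".join(f"({p[0]:g},{p[1]:g})" for p in r.ess),
                "basin_x": None if limit is None else limit[0],
                "basin_y": None if limit is None else limit[1],
                "patient_drift": r.patient_drift,
                "hospital_drift": r.hospital_drift,
            }
        )
    return pd.DataFrame(rows)


def phase_frame(field: PhaseField) -> pd.DataFrame:
    rows = []
    for i, yv in enumerate(field.y):
        for j, xv in enumerate(field.x):
            rows.append(
                {"x": xv, "y": yv, "dx_dt": field.dx[i, j], "dy_dt": field.dy[i, j]}
            )
    return pd.DataFrame(rows)


def _basin_summary(basin: BasinScanResult) -> dict[str, Any]:
    counts: dict[str, int] = {}
    for limit in basin.limits:
        key = "none" if limit is None else f"({limit[0]:g},{limit[1]:g})"
        counts[key] = counts.get(key, 0) + 1
    return {
        "n_runs": len(basin.grid),
        "n_converged": int(sum(basin.converged)),
        "unanimous": basin.unanimous,
        "unanimous_limit": _point(basin.unanimous_limit),
        "limit_counts": dict(sorted(counts.items())),
    }


def run_report(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis described by ``config`` and bundle it as JSON.

    The report contains the parameters and their constraint check, the
    equilibrium candidates, the corner stability table, the scenario
    classification, a basin-scan summary, and (if configured) a sweep.
    """
    params = config.parameters
    log.log(
        logging.getLevelName(config.log_level) if isinstance(
            logging.getLevelName(config.log_level), int) else logging.INFO,
        "analysing parameter set %s", params.as_dict(),
    )
    violations = validate_parameters(params, mode="warn")
    equilibria = enumerate_equilibria(params)
    stability = corner_stability_table(params)
    scenario = classify_scenario(params)
    ess = find_ess(params)
    grid = interior_grid(config.grid_step, config.grid_include_boundary)
    basin = basin_scan(params, grid, config.integration)

    report: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {k: _num(v) for k, v in params.as_dict().items()},
        "constraint_violations": [v.detail for v in violations],
        "equilibria": [
            {
                "name": p.name,
                "coords": [_num(p.coords[0]), _num(p.coords[1])],
                "kind": p.kind,
                "exists": p.exists,
                "degenerate_denominator": p.degenerate_denominator,
            }
            for p in equilibria
        ],
        "stability": [
            {
                "name": r.point.name,
                "coords": _point(r.point.coords),
                "jacobian": [[_num(v) for v in row] for row in r.jacobian],
                "det": _num(r.det),
                "trace": _num(r.trace),
                "classification": r.classification,
            }
            for r in stability
        ],
        "scenario": {
            "scenario_id": scenario.scenario_id,
            "boundary": scenario.boundary,
            "condition_values": {
                k: _num(v) for k, v in scenario.condition_values.items()
            },
            "predicted_ess": [_point(p) for p in scenario.predicted_ess],
        },
        "ess": [_point(p.coords) for p in ess],
        "basin_scan": _basin_summary(basin),
    }

    if config.sweep_parameter is not None:
        spec = SweepSpec(
            parameter=config.sweep_parameter,
            values=config.sweep_values,
            baseline=params,
            starts=tuple(grid),
            settings=config.integration,
        )
        result = sweep(spec)
        report["sweep"] = {
            "parameter": result.parameter,
            "values": [_num(v) for v in result.values],
            "records": [
                {
                    "value": _num(r.value),
                    "scenario_id": r.scenario.scenario_id,
                    "ess": [_point(p) for p in r.ess],
                    "basin_limit": _point(r.basin_limit),
                    "patient_drift": r.patient_drift,
                    "hospital_drift": r.hospital_drift,
                }
                for r in result.records
            ],
            "analytic_crossings": {
                k: _num(v) for k, v in sorted(result.analytic_crossings.items())
            },
            "notes": list(result.notes),
            "patient_switch": {
                "value": None if result.patient_switch.value is None
                else _num(result.patient_switch.value),
                "ambiguous": result.patient_switch.ambiguous,
            },
            "hospital_switch": {
                "value": None if result.hospital_switch.value is None
                else _num(result.hospital_switch.value),
                "ambiguous": result.hospital_switch.ambiguous,
            },
        }
    return report


def write_report(report: dict[str, Any], path: str | Path) -> Path:
    """Serialise a report deterministically (sorted keys, 12 sig. digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
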