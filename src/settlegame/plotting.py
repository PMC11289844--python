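"""Optional figure rendering (phase portraits and sweep line plots)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .dynamics import Trajectory, phase_field
from .model import GameParameters
from .sensitivity import SweepResult

__all__ = ["plot_phase_portrait", "plot_sweep"]


def plot_phase_portrait(
    params: GameParameters,
    resolution: int = 21,
    trajectories: Iterable[Trajectory] = (),
    path: str | Path | None = None,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Quiver plot of the replicator field with optional trajectory overlays."""
    field = phase_field(params, resolution)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.quiver(field.x, field.y, field.dx, field.dy, angles="xy", width=0.003)
    for traj in trajectories:
        ax.plot(traj.states[:, 0], traj.states[:, 1], lw=1.5)
        ax.plot(traj.states[0, 0], traj.states[0, 1], "o", ms=4)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("x (patients choosing cross-regional treatment)")
    ax.set_ylabel("y (hospitals settling directly)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_sweep(
    result: SweepResult, path: str | Path | None = None, ax: "plt.Axes | None" = None
) -> "plt.Axes":
    """Limiting coordinates of both populations versus the swept value."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    xs = list(result.values)
    patient = [
        None if r.basin_limit is None else r.basin_limit[0] for r in result.records
    ]
    hospital = [
        None if r.basin_limit is None else r.basin_limit[1] for r in result.records
    ]
    ax.plot(xs, patient, "o-", label="patient limit (x)")
    ax.plot(xs, hospital, "s--", label="hospital limit (y)")
    ax.set_xlabel(result.parameter)
    ax.set_ylabel("limiting frequency")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
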