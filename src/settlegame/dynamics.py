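"""Forward integration of the replicator system and basin scans.

The right-hand side is a smooth cubic polynomial on the unit square, so an
adaptive explicit Runge-Kutta pair is adequate (no stiffness).  Integration
proceeds in fixed-length windows; after each window the state is clipped to
the square (overshoot is bounded by the solver tolerance, since the square
is exactly invariant) and convergence is tested: a run has converged when
the state sits within ``conv_eps`` of a corner in the max norm and the
velocity's max norm is below ``stall_eps``.  Runs that reach ``t_max``
without satisfying both tests are reported unconverged — e.g. trajectories
attracted to a non-corner point of a degenerate edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp

from .model import GameParameters, PopulationState, rhs

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "BasinScanResult",
    "IntegrationError",
    "integrate",
    "basin_scan",
    "phase_field",
    "interior_grid",
    "PhaseField",
]

_CORNERS = ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0))


class IntegrationError(RuntimeError):
    """Solver failure; carries the partial trajectory."""

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass(frozen=True)
class IntegrationSettings:
    """Solver and convergence settings.

    rel_tol, abs_tol:
        Tolerances of the adaptive Runge-Kutta 4(5) integrator.  They must
        sit well below ``stall_eps``: near an attracting corner the
        numerical solution plateaus at a distance set by the solver
        tolerance, and the plateau velocity (distance times the local
        payoff advantage) has to fall under ``stall_eps`` for convergence
        to be declared.
    t_max:
        Horizon after which a run is declared unconverged.
    conv_eps:
        Max-norm radius around a corner within which convergence may be
        declared (must be < 0.5 so corners are unambiguous).
    stall_eps:
        Max-norm velocity threshold that must also be met.
    check_interval:
        Length of the integration windows between convergence tests.
    """

    rel_tol: float = 1e-10
    abs_tol: float = 1e-12
    t_max: float = 500.0
    conv_eps: float = 1e-4
    stall_eps: float = 1e-9
    check_interval: float = 25.0

    def __post_init__(self) -> None:
        for name in ("rel_tol", "abs_tol", "t_max", "conv_eps", "stall_eps",
                     "check_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.conv_eps >= 0.5:
            raise ValueError("conv_eps must be below 0.5")


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory with its convergence verdict.

    ``states`` are clipped to the unit square; ``max_overshoot`` records the
    largest raw excursion outside the square before clipping (a solver
    round-off diagnostic).  ``limit`` is the exact corner the run converged
    to, or None.
    """

    times: np.ndarray
    states: np.ndarray
    converged: bool
    limit: tuple[float, float] | None
    terminal_velocity: tuple[float, float]
    max_overshoot: float = 0.0

    @property
    def final(self) -> tuple[float, float]:
        return (float(self.states[-1, 0]), float(self.states[-1, 1]))


def _nearest_corner(x: float, y: float) -> tuple[tuple[float, float], float]:
    best, dist = _CORNERS[0], np.inf
    for c in _CORNERS:
        d = max(abs(x - c[0]), abs(y - c[1]))
        if d < dist:
            best, dist = c, d
    return best, dist


def _converged_at(
    params: GameParameters, x: float, y: float, settings: IntegrationSettings
) -> tuple[float, float] | None:
    corner, dist = _nearest_corner(x, y)
    if dist >= settings.conv_eps:
        return None
    dx, dy = rhs(params, x, y)
    if max(abs(dx), abs(dy)) < settings.stall_eps:
        return corner
    return None


def integrate(
    params: GameParameters,
    initial: PopulationState,
    settings: IntegrationSettings | None = None,
) -> Trajectory:
    """Integrate the replicator system from ``initial`` until convergence.

    Returns a :class:`Trajectory`; convergence means settling onto a corner
    (see module docstring).  Starting exactly at an equilibrium returns a
    constant trajectory immediately.
    """
    settings = settings or IntegrationSettings()
    x, y = initial.x, initial.y
    times = [0.0]
    states = [(x, y)]
    max_overshoot = 0.0

    corner = _converged_at(params, x, y, settings)
    t = 0.0
    while corner is None and t < settings.t_max:
        t_end = min(t + settings.check_interval, settings.t_max)
        sol = solve_ivp(
            lambda _t, s: rhs(params, s[0], s[1]),
            (t, t_end),
            (x, y),
            method="RK45",
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
        )
        if not sol.success:
            partial = Trajectory(
                times=np.asarray(times),
                states=np.asarray(states),
                converged=False,
                limit=None,
                terminal_velocity=rhs(params, x, y),
                max_overshoot=max_overshoot,
            )
            raise IntegrationError(f"solver failed: {sol.message}", partial)
        raw = sol.y.T  # (n, 2)
        overshoot = float(max(np.max(raw) - 1.0, -np.min(raw), 0.0))
        max_overshoot = max(max_overshoot, overshoot)
        clipped = np.clip(raw, 0.0, 1.0)
        times.extend(sol.t[1:].tolist())
        states.extend(map(tuple, clipped[1:]))
        x, y = float(clipped[-1, 0]), float(clipped[-1, 1])
        t = t_end
        corner = _converged_at(params, x, y, settings)

    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        converged=corner is not None,
        limit=corner,
        terminal_velocity=rhs(params, x, y),
        max_overshoot=max_overshoot,
    )


def interior_grid(step: float = 0.1, include_boundary: bool = False) -> list[PopulationState]:
    """The lattice {step, 2*step, ...}^2 of initial conditions.

    By default the grid stops short of 1.0: the faces x=1 and y=1 are
    invariant under replicator dynamics, so boundary starts trivially freeze
    one coordinate.  ``include_boundary`` restores the full lattice up to
    and including 1.0 for fidelity runs.
    """
    if not 0.0 < step < 1.0:
        raise ValueError("step must lie in (0, 1)")
    n = int(round((1.0 if include_boundary else 1.0 - step) / step))
    values = [round(step * k, 12) for k in range(1, n + 1)]
    return [PopulationState(x, y) for x in values for y in values]


@dataclass(frozen=True)
class BasinScanResult:
    """Limits of forward integration from a grid of initial conditions."""

    grid: tuple[PopulationState, ...]
    limits: tuple[tuple[float, float] | None, ...]
    finals: tuple[tuple[float, float], ...]
    converged: tuple[bool, ...]
    unanimous: bool
    unanimous_limit: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.limits) == len(self.finals)
                == len(self.converged)):
            raise ValueError("grid and result sequences must align")


def basin_scan(
    params: GameParameters,
    grid: Iterable[PopulationState] | None = None,
    settings: IntegrationSettings | None = None,
) -> BasinScanResult:
    """Integrate from each grid point and collect the corner limits.

    ``unanimous`` is True iff every run converged and all share a single
    corner limit; non-converged runs are recorded with limit None, never
    raised.
    """
    points = tuple(grid) if grid is not None else tuple(interior_grid())
    if not points:
        raise ValueError("empty initial-condition grid")
    settings = settings or IntegrationSettings()
    limits: list[tuple[float, float] | None] = []
    finals: list[tuple[float, float]] = []
    flags: list[bool] = []
    for point in points:
        traj = integrate(params, point, settings)
        limits.append(traj.limit)
        finals.append(traj.final)
        flags.append(traj.converged)
    distinct = {l for l in limits if l is not None}
    unanimous = all(flags) and len(distinct) == 1
    return BasinScanResult(
        grid=points,
        limits=tuple(limits),
        finals=tuple(finals),
        converged=tuple(flags),
        unanimous=unanimous,
        unanimous_limit=next(iter(distinct)) if unanimous else None,
    )


@dataclass(frozen=True)
class PhaseField:
    """Replicator velocities on a uniform lattice (for quiver plots)."""

    x: np.ndarray  # (resolution,)
    y: np.ndarray  # (resolution,)
    dx: np.ndarray  # (resolution, resolution), dx[i, j] at (x[j], y[i])
    dy: np.ndarray


def phase_field(params: GameParameters, resolution: int) -> PhaseField:
    """Velocities on the uniform ``resolution x resolution`` lattice over the square."""
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    xs = np.linspace(0.0, 1.0, resolution)
    ys = np.linspace(0.0, 1.0, resolution)
    dx = np.empty((resolution, resolution))
    dy = np.empty((resolution, resolution))
    for i, yv in enumerate(ys):
        for j, xv in enumerate(xs):
            dx[i, j], dy[i, j] = rhs(params, float(xv), float(yv))
    return PhaseField(x=xs, y=ys, dx=dx, dy=dy)
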