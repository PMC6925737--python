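"""Transport measurements: tracer-based mucus velocity and particle migration.

The mean mucus-layer (ML) velocity is estimated from passive tracepoints
seeded in the ML: each tracer's net x-displacement (kept unwrapped across
the periodic seam) over a fixed averaging window of 3 beat periods is
divided by the window length, averaged over tracers, and converted to
physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TracerSet", "mean_ml_velocity", "detect_developed_flow",
           "mean_particle_height"]


@dataclass
class TracerSet:
    """Passive tracepoints advected with the flow (unwrapped x)."""

    positions: np.ndarray            # (n, 2), x unwrapped
    window_periods: float = 3.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    @classmethod
    def seed(cls, n: int, y: float, channel_length: float,
             jitter: np.ndarray | None = None) -> "TracerSet":
        xs = (np.arange(n) + 0.5) * channel_length / n
        if jitter is not None:
            xs = xs + np.asarray(jitter, float)
        return cls(positions=np.column_stack([xs, np.full(n, float(y))]))


def mean_ml_velocity(x_start: np.ndarray, x_end: np.ndarray, window_steps: int,
                     dx_um: float, dt_s: float) -> float:
    """Tracer-mean transport velocity in micrometres per second.

    ``x_start``/``x_end`` are the unwrapped tracer x-positions at the two
    ends of the averaging window (lattice units), ``window_steps`` the window
    length in time steps, ``dx_um`` the physical size of one lattice unit in
    micrometres and ``dt_s`` the physical duration of one step in seconds.
    """
    if window_steps <= 0:
        raise ValueError("window must span at least one step")
    disp = np.asarray(x_end, float) - np.asarray(x_start, float)
    v_lat = float(np.mean(disp)) / window_steps
    return v_lat * dx_um / dt_s


def detect_developed_flow(per_period_velocity: np.ndarray, rel_tol: float = 0.02,
                          fallback_fraction: float = 2 / 3) -> int:
    """Index of the first beat period after which the flow is developed.

    Returns the earliest period index k such that every later pair of
    consecutive per-period mean velocities differs by less than ``rel_tol``
    relative to their magnitude.  If the log never settles, falls back to
    ``fallback_fraction`` of its length (and the caller should log a
    warning).
    """
    v = np.asarray(per_period_velocity, dtype=float)
    if v.size < 2:
        return 0
    scale = np.maximum(np.abs(v[1:]), np.abs(v[:-1]))
    ok = np.abs(np.diff(v)) < rel_tol * np.where(scale > 0, scale, 1.0)
    # earliest k with ok[k:] all true
    settled = np.flatnonzero(~ok)
    if settled.size == 0:
        return 1
    k = int(settled[-1]) + 2
    if k >= v.size:
        return int(np.ceil(fallback_fraction * v.size))
    return k


def mean_particle_height(trajectories: np.ndarray, dx_um: float) -> np.ndarray:
    """Mean particle y-trajectory in micrometres.

    ``trajectories`` has shape (n_times, n_particles) holding y-positions in
    node-index lattice coordinates (bottom wall at -1/2); converts to
    physical height above the wall.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 2 or traj.shape[1] < 1:
        raise ValueError("need at least one particle trajectory")
    return (traj.mean(axis=1) + 0.5) * dx_um
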