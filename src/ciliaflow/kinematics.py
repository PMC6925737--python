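"""Ciliary beat waveform generation and cilia-array layout.

The virtual cilium follows a prescribed planar two-stroke beat:

* **effective stroke** (fraction ``asymmetry`` of the cycle): the cilium is
  straight and pivots about its root from ``-amplitude`` to ``+amplitude``
  (angles from the vertical), sweeping its extended length through the fluid;
* **recovery stroke**: the root angle swings back while a curvature wave
  curls the distal part over, returning the cilium with a low tip —
  the classic low-Reynolds asymmetry that makes the tip path enclose area
  and produces net pumping.

Postures are built from the tangent-angle profile, so every posture has
exactly the cilium arclength L by construction.  An array of cilia applies a
constant inter-cilium phase offset, which forms a metachronal wave; the
channel is periodic, so the total phase advance around the array must close
to an integer number of cycles (the channel length is adjusted to allow it).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

__all__ = ["BeatWaveform", "CiliaArray", "default_beat_generator",
           "load_beat_table", "save_beat_table", "build_cilia_array",
           "adjust_channel_length"]


@dataclass(frozen=True)
class BeatWaveform:
    """Sampled beat postures Y(s, phi) over one unit cycle.

    ``table`` has shape (n_phase, n_nodes, 2) with the root at the origin;
    phase phi is periodic with period 1 and interpolated linearly between
    samples.
    """

    table: np.ndarray
    frequency_hz: float = 20.0
    amplitude: float = 0.0   # generator parameter, kept for provenance

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 3 or t.shape[2] != 2:
            raise ValueError("table must be (n_phase, n_nodes, 2)")
        if t.shape[0] < 2:
            raise ValueError("cycle undefined: need at least 2 phase samples")
        root = t[:, 0, :]
        if not np.allclose(root, root[0], atol=1e-9):
            raise ValueError("root node must be fixed across the cycle")
        seg = np.linalg.norm(np.diff(t, axis=1), axis=2)
        arclen = seg.sum(axis=1)
        L = arclen.mean()
        if np.any(np.abs(arclen - L) > 0.01 * L):
            raise ValueError("posture arclength varies by more than 1%")
        object.__setattr__(self, "table", t)

    @property
    def n_phase(self) -> int:
        return self.table.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.table.shape[1]

    @property
    def length(self) -> float:
        seg = np.linalg.norm(np.diff(self.table[0], axis=0), axis=1)
        return float(seg.sum())

    def posture(self, phase: float) -> np.ndarray:
        """Posture at an arbitrary phase (linear interpolation, periodic)."""
        x = (phase % 1.0) * self.n_phase
        i0 = int(np.floor(x)) % self.n_phase
        i1 = (i0 + 1) % self.n_phase
        w = x - np.floor(x)
        return (1.0 - w) * self.table[i0] + w * self.table[i1]

    def mean_tip_speed(self, period_steps: int) -> float:
        """Cycle-averaged tip speed in lattice units per step."""
        tip = self.table[:, -1, :]
        d = np.diff(np.vstack([tip, tip[:1]]), axis=0)
        path = np.hypot(d[:, 0], d[:, 1]).sum()
        return float(path / period_steps)

    def tip_path_area(self) -> float:
        """Signed shoelace area enclosed by the tip trajectory."""
        tip = self.table[:, -1, :]
        x, y = tip[:, 0], tip[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def default_beat_generator(n_nodes: int, length: float, amplitude: float,
                           asymmetry: float = 0.35, curl: float = 2.5,
                           n_phase: int = 128, frequency_hz: float = 20.0,
                           max_tip_height: float | None = None) -> BeatWaveform:
    """Generate the two-stroke asymmetric beat described in the module docs.

    Parameters
    ----------
    n_nodes : nodes per cilium.
    length : cilium arclength L in lattice units.
    amplitude : half-angle of the root sweep, radians (>= 0).
    asymmetry : effective-stroke fraction of the cycle, in (0, 1).
    curl : recovery-stroke folding angle (radians) accumulated along the
        cilium at mid-recovery.  A real cilium folds over during its
        recovery stroke regardless of how wide it sweeps, so the curl does
        not scale with ``amplitude``; it vanishes smoothly at the stroke
        ends so the beat stays continuous.
    max_tip_height : optional ceiling for the tip (configuration check).

    ``amplitude = 0`` degenerates to the motionless vertical cilium (useful
    as a zero-forcing control).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if not 0.05 < asymmetry < 0.95:
        raise ValueError("asymmetry must lie in (0.05, 0.95)")
    ds = length / (n_nodes - 1)
    s_frac = np.arange(n_nodes - 1) / (n_nodes - 1)  # fractional arclength per segment
    table = np.zeros((n_phase, n_nodes, 2))
    for p in range(n_phase):
        phi = p / n_phase
        if phi < asymmetry:
            psi = -amplitude * np.cos(np.pi * phi / asymmetry)
            bend = 0.0
        else:
            phit = (phi - asymmetry) / (1.0 - asymmetry)
            psi = amplitude * np.cos(np.pi * phit)
            bend = curl * np.sin(np.pi * phit) if amplitude > 0 else 0.0
        # tangent angle from vertical; the recovery fold is weighted toward
        # the distal half (quadratic tangent-angle profile), so the tip
        # curls over while the base finishes its return sweep
        alpha = psi + bend * s_frac ** 2
        x = np.concatenate([[0.0], np.cumsum(np.sin(alpha) * ds)])
        y = np.concatenate([[0.0], np.cumsum(np.cos(alpha) * ds)])
        table[p, :, 0] = x
        table[p, :, 1] = y
    if max_tip_height is not None and table[:, -1, 1].max() > max_tip_height:
        raise ValueError("beat amplitude drives the tip above the channel")
    return BeatWaveform(table=table, frequency_hz=frequency_hz,
                        amplitude=float(amplitude))


def save_beat_table(wf: BeatWaveform, path: str | Path) -> None:
    """Write a waveform as CSV rows (phase_index, node_index, x, y)."""
    n_phase, n_nodes = wf.n_phase, wf.n_nodes
    with open(path, "w") as fh:
        fh.write("phase_index,node_index,x,y\n")
        for p in range(n_phase):
            for j in range(n_nodes):
                fh.write(f"{p},{j},{float(wf.table[p, j, 0])!r},"
                         f"{float(wf.table[p, j, 1])!r}\n")


def load_beat_table(path: str | Path, frequency_hz: float = 20.0) -> BeatWaveform:
    """Load a beat table CSV and validate the waveform invariants."""
    raw = np.loadtxt(path, delimiter=",", skiprows=1)
    if raw.ndim != 2 or raw.shape[1] != 4:
        raise ValueError("beat table must have columns phase_index,node_index,x,y")
    n_phase = int(raw[:, 0].max()) + 1
    n_nodes = int(raw[:, 1].max()) + 1
    if n_phase < 2:
        raise ValueError("cycle undefined: single-phase table rejected")
    table = np.full((n_phase, n_nodes, 2), np.nan)
    table[raw[:, 0].astype(int), raw[:, 1].astype(int), :] = raw[:, 2:4]
    if np.any(np.isnan(table)):
        raise ValueError("beat table is missing (phase, node) entries")
    return BeatWaveform(table=table, frequency_hz=frequency_hz)


def adjust_channel_length(spacing: float, phase_diff: float,
                          target_length: float, max_factor: float = 8.0
                          ) -> tuple[int, float]:
    """Choose the cilium count and channel length compatible with periodicity.

    Picks ``n_cilia`` minimizing ``|n * spacing - target_length|`` subject to
    ``(n * phase_diff) mod 1 == 0`` so the metachronal phase pattern closes
    around the periodic channel, searching ``n <= max_factor * n_default``.
    Returns ``(n_cilia, channel_length)``.  Raises if no admissible count
    exists in range.
    """
    if spacing <= 0 or phase_diff < 0:
        raise ValueError("spacing must be positive and phase_diff nonnegative")
    n_default = max(1, round(target_length / spacing))
    n_max = max(n_default, int(np.ceil(max_factor * n_default)))
    if phase_diff == 0:
        return n_default, n_default * spacing
    frac = Fraction(phase_diff).limit_denominator(10_000)
    q = frac.denominator
    feasible = [n for n in range(q, n_max + 1, q)]
    if not feasible:
        raise ValueError(
            f"no cilium count <= {n_max} closes phase difference {phase_diff}")
    n = min(feasible, key=lambda m: (abs(m * spacing - target_length), m))
    return n, n * spacing


@dataclass(frozen=True)
class CiliaArray:
    """Layout of the cilia array in a periodic channel.

    Cilium k is rooted at ``x_k = k * spacing`` on the bottom wall and beats
    with phase ``(t/T + k * phase_diff) mod 1``; the constant offset between
    neighbours forms a metachronal wave of speed ``spacing / phase_diff``
    (lattice units per beat period).
    """

    n_cilia: int
    spacing: float
    phase_diff: float
    channel_length: float

    def root(self, k: int) -> np.ndarray:
        return np.array([k * self.spacing, 0.0])

    def phases(self, t_over_T: float) -> np.ndarray:
        k = np.arange(self.n_cilia)
        return (t_over_T + k * self.phase_diff) % 1.0


def build_cilia_array(spacing: float, phase_diff: float, target_length: float,
                      min_spacing: float = 2.0, snap_phase: bool = False
                      ) -> CiliaArray:
    """Lay out the cilia array, adjusting the channel for phase closure.

    With ``snap_phase=True`` the cilium count is fixed at the default tiling
    and the phase difference is instead snapped to the nearest closing value
    ``round(n * phase_diff) / n`` (used when an exact-closure channel would
    be impractically long).
    """
    if spacing < min_spacing:
        raise ValueError(f"cilium spacing {spacing} below minimum {min_spacing}")
    if snap_phase and phase_diff > 0:
        n = max(1, round(target_length / spacing))
        snapped = round(n * phase_diff) / n
        return CiliaArray(n_cilia=n, spacing=spacing, phase_diff=snapped,
                          channel_length=n * spacing)
    n, length = adjust_channel_length(spacing, phase_diff, target_length)
    return CiliaArray(n_cilia=n, spacing=spacing, phase_diff=phase_diff,
                      channel_length=length)
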