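"""Simulation configuration: physical parameters and their lattice resolution.

All inputs are physical or nondimensional (micrometres, Hz, Reynolds /
Weissenberg numbers); :func:`resolve` maps them onto lattice units.
Conventions (the reference publication of this model family leaves the
scales open, so they are fixed here and logged with every run):

* 1 lattice unit corresponds to ``dx_um`` micrometres; the solver itself
  always uses dx = dt = 1.
* the beat period T is resolved by ``steps_per_period`` time steps; the
  default scales as ``5000 * (0.4 / dx_um)^2`` so that lattice velocities
  (and with them the fiber tensions, which must respect the +/-1% strain
  budget of the Ks = 2.0 springs) are resolution independent.
* Re = U_tip * L / nu_ML with U_tip the cycle-mean virtual-cilium tip speed
  and nu_ML the total mucus-layer kinematic viscosity; the PCL viscosity
  follows from the ML:PCL ratio.
* We = lambda * f, i.e. the stress relaxation time in units of the beat
  period.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kinematics import BeatWaveform, CiliaArray, build_cilia_array, default_beat_generator

__all__ = ["ParticleSpec", "SimulationConfig", "ResolvedParams", "resolve",
           "load_config", "save_config"]


@dataclass(frozen=True)
class ParticleSpec:
    """Rigid-particle seeding for one run."""

    n: int = 20
    diameter_um: float = 0.4
    y0_um: float = 4.5
    rho_p: float = 1.0
    repulsion_strength: float = 0.012
    repulsion_cutoff: float = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one mucociliary-clearance run."""

    # resolution
    dx_um: float = 0.4
    steps_per_period: int | None = None
    # geometry (micrometres)
    pcl_depth_um: float = 6.2
    ml_thickness_um: float = 4.0
    channel_length_um: float = 60.0
    cilium_length_um: float = 5.5
    # dimensionless flow parameters
    reynolds: float = 0.05
    weissenberg: float = 0.01
    viscosity_ratio: float = 40.0
    rv: float = 0.975
    # cilia array and beat
    beat_frequency_hz: float = 20.0
    spacing_L: float = 0.55
    phase_diff_T: float = 0.02
    snap_phase: bool = False
    amplitude: float = 0.230
    mirror_beat: bool = False
    asymmetry: float = 0.35
    curl: float = 2.5
    n_phase: int = 128
    # structural coefficients (nondimensional, lattice units)
    Ks: float = 2.0
    Kb: float = 1.0
    Ksl: float = 1.0
    # numerics
    min_pcl_viscosity: float = 0.1   # lattice floor: tau_PCL >= 0.8, quasi-steady beat
    # measurement
    n_tracers: int = 50
    total_periods: float = 10.0
    window_periods: float = 3.0
    # particles
    particles: ParticleSpec | None = None
    # misc
    seed: int = 0
    record_every_steps: int | None = None

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ResolvedParams:
    """Lattice-unit quantities derived from a :class:`SimulationConfig`."""

    nx: int
    ny: int
    steps_per_period: int
    cilium_length: float
    n_nodes: int
    ds: float
    membrane_y: float          # node-index coordinates (wall at -1/2)
    array: CiliaArray
    waveform: BeatWaveform
    u_tip: float
    nu_ml: float
    nu_pcl: float
    eta_e: float
    lambda_relax: float
    tau_ml: float
    tau_pcl: float
    dt_s: float
    dx_um: float

    def summary(self) -> dict:
        d = {
            "nx": self.nx, "ny": self.ny,
            "steps_per_period": self.steps_per_period,
            "n_cilia": self.array.n_cilia,
            "spacing_lat": self.array.spacing,
            "phase_diff_T": self.array.phase_diff,
            "cilium_length_lat": self.cilium_length,
            "u_tip_lat": self.u_tip,
            "nu_ml": self.nu_ml, "nu_pcl": self.nu_pcl,
            "tau_ml": self.tau_ml, "tau_pcl": self.tau_pcl,
            "eta_e": self.eta_e, "lambda_relax": self.lambda_relax,
            "reynolds_effective": self.u_tip * self.cilium_length / self.nu_ml,
            "dt_s": self.dt_s, "dx_um": self.dx_um,
        }
        return d


def resolve(cfg: SimulationConfig) -> ResolvedParams:
    """Map a physical configuration onto lattice units.

    The channel length is adjusted (via the cilia-array layout) so that the
    metachronal phase pattern closes around the periodic channel, then
    rounded to an integer number of lattice columns.
    """
    dx = cfg.dx_um
    T = cfg.steps_per_period or round(5000 * (0.4 / dx) ** 2)
    L = cfg.cilium_length_um / dx
    n_nodes = int(round(L)) + 1
    ds = L / (n_nodes - 1)
    array = build_cilia_array(cfg.spacing_L * L, cfg.phase_diff_T,
                              cfg.channel_length_um / dx,
                              snap_phase=cfg.snap_phase)
    nx = int(round(array.channel_length))
    # snap the spacing so n_cilia * spacing == nx exactly
    array = CiliaArray(n_cilia=array.n_cilia, spacing=nx / array.n_cilia,
                       phase_diff=array.phase_diff, channel_length=float(nx))
    ny = int(round((cfg.pcl_depth_um + cfg.ml_thickness_um) / dx))
    membrane_y = cfg.pcl_depth_um / dx - 0.5
    wf = default_beat_generator(n_nodes, L, cfg.amplitude, cfg.asymmetry,
                                cfg.curl, cfg.n_phase, cfg.beat_frequency_hz,
                                max_tip_height=ny - 0.5)
    if cfg.mirror_beat:
        # x-reflected beat: mirrored postures, reversed metachronal direction
        from .kinematics import BeatWaveform
        wf = BeatWaveform(table=wf.table * np.array([-1.0, 1.0]),
                          frequency_hz=wf.frequency_hz, amplitude=wf.amplitude)
        array = CiliaArray(n_cilia=array.n_cilia, spacing=array.spacing,
                           phase_diff=-array.phase_diff,
                           channel_length=array.channel_length)
    u_tip = wf.mean_tip_speed(T)
    nu_ml = u_tip * L / cfg.reynolds
    nu_pcl = nu_ml / cfg.viscosity_ratio
    if nu_pcl < cfg.min_pcl_viscosity:
        # keep the ML:PCL ratio; the effective Reynolds number drops below
        # the configured one (deeper into the Stokes regime, where transport
        # per beat is insensitive to Re)
        nu_pcl = cfg.min_pcl_viscosity
        nu_ml = nu_pcl * cfg.viscosity_ratio
    tau_pcl = 0.5 + 3.0 * nu_pcl
    tau_ml = 0.5 + 3.0 * cfg.rv * nu_ml
    if tau_pcl < 0.505:
        raise ValueError(
            f"PCL relaxation time {tau_pcl:.4f} too close to 1/2; "
            "increase steps_per_period or the Reynolds number")
    eta_e = (1.0 - cfg.rv) * nu_ml  # rho = 1
    lam = cfg.weissenberg * T
    return ResolvedParams(nx=nx, ny=ny, steps_per_period=T, cilium_length=L,
                          n_nodes=n_nodes, ds=ds, membrane_y=membrane_y,
                          array=array, waveform=wf, u_tip=u_tip, nu_ml=nu_ml,
                          nu_pcl=nu_pcl, eta_e=eta_e, lambda_relax=lam,
                          tau_ml=tau_ml, tau_pcl=tau_pcl,
                          dt_s=1.0 / (cfg.beat_frequency_hz * T), dx_um=dx)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    if cfg.particles is not None:
        d["particles"] = dataclasses.asdict(cfg.particles)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if d.get("particles") is not None:
        d["particles"] = ParticleSpec(**d["particles"])
    return SimulationConfig(**d)
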