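"""Rigid circular particles suspended in the periciliary liquid.

Each particle is a rigid disc discretized by surface Lagrangian points.  The
hydrodynamic surface-traction integral of the rigid-body equations is
realized by direct-forcing momentum exchange: a penalty force drives the
interpolated fluid velocity at every surface point toward the rigid-body
velocity ``U_p + Omega_p x r``; the accumulated reaction (and its moment)
is, at the discrete level, the traction integral acting on the particle.
Short-range quadratic repulsion keeps particles from interpenetrating each
other, the walls, and the cilia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .immersed import DeltaKernel, PESKIN4, interpolate_velocity, spread_force

__all__ = ["RigidParticle", "seed_particles", "repulsive_force",
           "particle_fluid_forces", "advance_particle"]


@dataclass
class RigidParticle:
    """Rigid disc with translational and angular state.

    Surface points are regenerated from ``(Xc, angle)`` every step, so the
    boundary stays an exact circle by construction.  ``beta`` scales the
    direct-forcing penalty (per unit surface length, per step).
    """

    Xc: np.ndarray
    diameter: float
    rho_p: float = 1.0
    Up: np.ndarray = field(default_factory=lambda: np.zeros(2))
    Omega_p: float = 0.0
    angle: float = 0.0
    n_surface: int = 0
    beta: float = 1.0
    removed: bool = False

    def __post_init__(self) -> None:
        self.Xc = np.asarray(self.Xc, dtype=float)
        self.Up = np.asarray(self.Up, dtype=float)
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.n_surface == 0:
            self.n_surface = max(8, int(np.ceil(np.pi * self.diameter)))

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def mass(self) -> float:
        return self.rho_p * np.pi * self.radius ** 2

    @property
    def inertia(self) -> float:
        """Moment of inertia of a disc: m r^2 / 2."""
        return 0.5 * self.mass * self.radius ** 2

    @property
    def ds(self) -> float:
        """Surface quadrature weight per point."""
        return np.pi * self.diameter / self.n_surface

    def surface_points(self) -> np.ndarray:
        th = self.angle + 2.0 * np.pi * np.arange(self.n_surface) / self.n_surface
        return self.Xc + self.radius * np.column_stack([np.cos(th), np.sin(th)])

    def surface_velocities(self) -> np.ndarray:
        r = self.surface_points() - self.Xc
        return self.Up + self.Omega_p * np.column_stack([-r[:, 1], r[:, 0]])


def seed_particles(n: int, diameter: float, y0: float, channel_length: float,
                   rho_p: float = 1.0, jitter: np.ndarray | None = None
                   ) -> list[RigidParticle]:
    """Place ``n`` particles evenly spaced in x at height ``y0``, at rest.

    ``jitter`` optionally perturbs the x positions (same length as ``n``);
    spacing must leave the discs non-overlapping and ``y0`` must clear the
    bottom wall (at y = -1/2 in node coordinates).
    """
    if y0 - 0.5 * diameter < -0.5:
        raise ValueError("seed height would intersect the bottom wall")
    spacing = channel_length / n
    if spacing <= diameter:
        raise ValueError("requested seeding overlaps neighbouring particles")
    xs = (np.arange(n) + 0.5) * spacing
    if jitter is not None:
        xs = xs + np.clip(np.asarray(jitter, float), -0.25 * spacing, 0.25 * spacing)
    return [RigidParticle(Xc=np.array([x, y0]), diameter=diameter, rho_p=rho_p)
            for x in xs]


def _pair_repulsion(gap: float, direction: np.ndarray, strength: float,
                    cutoff: float) -> np.ndarray:
    if gap >= cutoff:
        return np.zeros(2)
    g = max(gap, 0.0)  # interpenetration: cap the force at its maximum
    return strength * ((cutoff - g) / cutoff) ** 2 * direction


def repulsive_force(particle: RigidParticle, others=(), fiber_points=None,
                    wall_y=(-0.5, None), strength: float = 0.05,
                    cutoff: float = 2.0):
    """Short-range repulsion from other particles, fiber nodes and the walls.

    Force model: ``C ((d_cut - d)/d_cut)^2 n_hat`` on the surface gap ``d``,
    zero beyond ``d_cut``.  Returns ``(force, reactions)`` where ``reactions``
    maps fiber-point indices to the equal-and-opposite share delivered to
    the fiber (empty when ``fiber_points`` is None).
    """
    F = np.zeros(2)
    reactions: dict[int, np.ndarray] = {}
    r = particle.radius
    for other in others:
        if other is particle or other.removed:
            continue
        d = particle.Xc - other.Xc
        dist = np.hypot(*d)
        if dist < 1e-12:
            continue
        gap = dist - r - other.radius
        F += _pair_repulsion(gap, d / dist, strength, cutoff)
    ybot, ytop = wall_y
    if ybot is not None:
        gap = particle.Xc[1] - r - ybot
        F += _pair_repulsion(gap, np.array([0.0, 1.0]), strength, cutoff)
        if gap < -r:
            raise FloatingPointError("particle overlapping the wall beyond repulsion range")
    if ytop is not None:
        gap = ytop - particle.Xc[1] - r
        F += _pair_repulsion(gap, np.array([0.0, -1.0]), strength, cutoff)
    if fiber_points is not None and len(fiber_points):
        pts = np.asarray(fiber_points, float)
        d = particle.Xc[None, :] - pts
        dist = np.hypot(d[:, 0], d[:, 1])
        gap = dist - r
        close = np.nonzero(gap < cutoff)[0]
        for idx in close:
            if dist[idx] < 1e-12:
                continue
            f = _pair_repulsion(gap[idx], d[idx] / dist[idx], strength, cutoff)
            F += f
            reactions[int(idx)] = -f
    return F, reactions


def particle_fluid_forces(particle: RigidParticle, u_field: np.ndarray,
                          kernel: DeltaKernel = PESKIN4, dt: float = 1.0,
                          rho_f: float = 1.0, f_out: np.ndarray | None = None):
    """Direct-forcing momentum exchange between the disc and the fluid.

    The penalty force density at each surface point is
    ``f = beta * rho_f * (U_rigid - U_interp) / dt``; it is spread onto the
    lattice (into ``f_out`` if given) and its accumulated opposite, with
    moments, is returned as ``(F_hydro, T_hydro)`` acting on the particle.
    """
    pts = particle.surface_points()
    u_interp = interpolate_velocity(u_field, pts, kernel)
    f_pts = particle.beta * rho_f * (particle.surface_velocities() - u_interp) / dt
    if f_out is not None:
        spread_force(pts, f_pts, f_out.shape[1:], kernel, ds=particle.ds, out=f_out)
    F_hydro = -f_pts.sum(axis=0) * particle.ds
    r = pts - particle.Xc
    T_hydro = -np.sum(r[:, 0] * f_pts[:, 1] - r[:, 1] * f_pts[:, 0]) * particle.ds
    return F_hydro, T_hydro


def advance_particle(particle: RigidParticle, F_total: np.ndarray, T_total: float,
                     dt: float = 1.0, domain_ny: int | None = None) -> RigidParticle:
    """Explicit Newton update: velocities first, then positions (in place)."""
    particle.Up = particle.Up + np.asarray(F_total, float) / particle.mass * dt
    particle.Omega_p = particle.Omega_p + T_total / particle.inertia * dt
    particle.Xc = particle.Xc + particle.Up * dt
    particle.angle += particle.Omega_p * dt
    if domain_ny is not None and not (-0.5 <= particle.Xc[1] <= domain_ny - 0.5):
        particle.removed = True
    return particle
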