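"""Rigid-particle mechanics: seeding, contact forces, dynamics, hydrodynamics."""

import numpy as np
import pytest

from ciliaflow.lattice import (BoundarySpec, FluidField, LatticeSpec,
                               collide_stream, equilibrium, macroscopic)
from ciliaflow.particles import (RigidParticle, advance_particle,
                                 particle_fluid_forces, repulsive_force,
                                 seed_particles)


class TestSeeding:
    def test_twenty_particles_seed_at_requested_height(self):
        # 0.4 um discs at 4.5 um in a 60 um channel at dx = 0.1 um
        parts = seed_particles(20, diameter=4.0, y0=44.5, channel_length=600.0)
        assert len(parts) == 20
        ys = {p.Xc[1] for p in parts}
        assert ys == {44.5}
        xs = sorted(p.Xc[0] for p in parts)
        gaps = np.diff(xs)
        assert np.all(gaps > 4.0)

    def test_single_particle_centers_in_channel(self):
        (p,) = seed_particles(1, 4.0, 10.0, 100.0)
        assert p.Xc[0] == pytest.approx(50.0)
        assert np.allclose(p.Up, 0.0) and p.Omega_p == 0.0

    def test_wall_intersecting_height_rejected(self):
        with pytest.raises(ValueError):
            seed_particles(5, 4.0, 1.0, 100.0)

    def test_overlapping_spacing_rejected(self):
        with pytest.raises(ValueError):
            seed_particles(30, 4.0, 10.0, 100.0)

    def test_disc_inertia(self):
        (p,) = seed_particles(1, 4.0, 10.0, 100.0)
        assert p.inertia == pytest.approx(0.5 * p.mass * 2.0 ** 2)


class TestAdvance:
    def test_force_free_motion_is_uniform(self):
        p = RigidParticle(Xc=[5.0, 5.0], diameter=4.0, Up=np.array([0.01, 0.0]),
                          Omega_p=0.002)
        for _ in range(10):
            advance_particle(p, np.zeros(2), 0.0)
        assert p.Xc[0] == pytest.approx(5.0 + 0.1)
        assert p.Omega_p == pytest.approx(0.002)

    def test_constant_force_gives_discrete_quadratic_trajectory(self):
        p = RigidParticle(Xc=[0.0, 10.0], diameter=2.0)
        F = np.array([1e-4, 0.0])
        n = 50
        for _ in range(n):
            advance_particle(p, F, 0.0)
        # velocity-first Euler: x(n) = (F/m) n(n+1)/2
        assert p.Xc[0] == pytest.approx(F[0] / p.mass * n * (n + 1) / 2, rel=1e-12)

    def test_surface_stays_exactly_rigid(self, rng):
        p = RigidParticle(Xc=[8.0, 8.0], diameter=5.0)
        for _ in range(1000):
            advance_particle(p, rng.standard_normal(2) * 1e-4,
                             rng.standard_normal() * 1e-5)
        r = np.linalg.norm(p.surface_points() - p.Xc, axis=1)
        assert np.allclose(r, 2.5, atol=1e-12)

    def test_escaping_particle_is_flagged(self):
        p = RigidParticle(Xc=[5.0, 1.0], diameter=1.0,
                          Up=np.array([0.0, -2.0]))
        advance_particle(p, np.zeros(2), 0.0, domain_ny=20)
        assert p.removed


class TestRepulsion:
    def test_no_force_beyond_cutoff(self):
        a = RigidParticle(Xc=[5.0, 10.0], diameter=2.0)
        b = RigidParticle(Xc=[12.0, 10.0], diameter=2.0)
        F, _ = repulsive_force(a, others=[b], wall_y=(None, None))
        assert np.allclose(F, 0.0)

    def test_pair_forces_equal_and_opposite_along_center_line(self):
        a = RigidParticle(Xc=[5.0, 10.0], diameter=2.0)
        b = RigidParticle(Xc=[8.0, 10.0], diameter=2.0)  # gap = 1 < cutoff 2
        Fa, _ = repulsive_force(a, others=[b], wall_y=(None, None))
        Fb, _ = repulsive_force(b, others=[a], wall_y=(None, None))
        assert np.allclose(Fa, -Fb)
        assert Fa[1] == 0.0 and Fa[0] < 0.0

    def test_fiber_contact_returns_opposite_reaction(self):
        a = RigidParticle(Xc=[5.0, 5.0], diameter=2.0)
        pts = np.array([[5.0, 3.5], [20.0, 3.5]])
        F, reactions = repulsive_force(a, fiber_points=pts, wall_y=(None, None))
        assert F[1] > 0.0
        assert set(reactions) == {0}
        assert np.allclose(reactions[0], -F)

    def test_wall_hover_without_interpenetration(self):
        # pushed toward the bottom wall, the particle settles hovering in
        # the repulsion range without ever crossing the wall
        p = RigidParticle(Xc=[5.0, 4.0], diameter=2.0)
        push = np.array([0.0, -2e-4])
        gap_min = np.inf
        for _ in range(10_000):
            F, _ = repulsive_force(p, wall_y=(-0.5, None), strength=0.05)
            drag = -0.05 * p.Up * p.mass     # simple damping stand-in for fluid
            advance_particle(p, F + push + drag, 0.0)
            gap_min = min(gap_min, p.Xc[1] - 1.0 - (-0.5))
        gap = p.Xc[1] - 1.0 - (-0.5)
        assert 0.0 < gap < 2.0
        assert gap_min > 0.0


class TestHydrodynamics:
    def _fluid(self, ny, nx, tau, u0=(0.0, 0.0), shear=None):
        spec = LatticeSpec(nx, ny)
        f = FluidField.uniform(spec, tau=tau, u=u0)
        if shear is not None:
            f.u[0] = shear * (np.arange(ny)[:, None] - (ny - 1) / 2)
            f.g = equilibrium(f.rho, f.u, spec)
        return spec, f

    def test_rest_particle_in_quiescent_fluid_feels_nothing(self):
        spec, fl = self._fluid(20, 20, 0.8)
        p = RigidParticle(Xc=[10.0, 10.0], diameter=6.0)
        F, T = particle_fluid_forces(p, fl.u)
        assert np.allclose(F, 0.0, atol=1e-14)
        assert T == pytest.approx(0.0, abs=1e-14)

    def test_momentum_exchange_is_action_reaction(self):
        spec, fl = self._fluid(20, 20, 0.8, u0=(0.01, 0.0))
        p = RigidParticle(Xc=[10.0, 10.0], diameter=6.0)
        f_out = np.zeros((2, 20, 20))
        F, T = particle_fluid_forces(p, fl.u, f_out=f_out)
        assert np.allclose(f_out.sum(axis=(1, 2)), -F, atol=1e-10)

    def test_drag_opposes_relative_motion(self):
        spec, fl = self._fluid(24, 24, 1.0, u0=(0.02, 0.0))
        p = RigidParticle(Xc=[12.0, 12.0], diameter=8.0)
        F, _ = particle_fluid_forces(p, fl.u)
        assert F[0] > 0.0                  # dragged along with the stream
        assert abs(F[1]) < 0.05 * F[0]

    def test_freely_suspended_disc_rotates_at_half_shear_rate(self):
        """A torque-free disc in simple shear spins with the local vorticity.

        For u_x = gdot * y the vorticity is -gdot, so the disc settles at
        Omega = -gdot/2 (the planar Jeffery limit for a circular cylinder).
        """
        gdot = 2e-3
        ny, nx = 40, 40
        spec, fl = self._fluid(ny, nx, 1.0, shear=gdot)
        bc = BoundarySpec(bottom="noslip_neq", top="noslip_neq")
        p = RigidParticle(Xc=[20.0, 19.5], diameter=10.0)
        u_wall = gdot * (ny - 1) / 2
        prof = np.zeros((2, ny))
        prof[0] = gdot * (np.arange(ny) - (ny - 1) / 2)
        for step in range(4000):
            fl.f_body[:] = 0.0
            F, T = particle_fluid_forces(p, fl.u, f_out=fl.f_body)
            collide_stream(fl, spec, bc)
            # re-impose the moving-wall rows to sustain the shear
            fl.g[:, 0, :] = equilibrium(np.full(nx, 1.0),
                                        np.array([[-u_wall] * nx, [0.0] * nx]),
                                        spec)
            fl.g[:, -1, :] = equilibrium(np.full(nx, 1.0),
                                         np.array([[u_wall] * nx, [0.0] * nx]),
                                         spec)
            macroscopic(fl, spec)
            p.Omega_p += T / p.inertia
            p.angle += p.Omega_p
            p.Up[:] = 0.0                  # held at the center, free to spin
        assert p.Omega_p == pytest.approx(-gdot / 2, rel=0.10)
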