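"""D2Q9 core: equilibrium moments, forcing, streaming, boundaries, viscosity."""

import numpy as np
import pytest

from ciliaflow.fixtures import make_analytic_field
from ciliaflow.lattice import (E, W, BoundarySpec, FluidField, LatticeSpec,
                               apply_boundaries, collide_stream, equilibrium,
                               guo_source, macroscopic)


def test_weight_and_velocity_moment_identities(unit_spec):
    cs2 = unit_spec.cs ** 2
    assert W.sum() == pytest.approx(1.0, abs=1e-15)
    assert np.allclose(W @ E, 0.0)
    second = np.einsum("i,ia,ib->ab", W, E.astype(float), E.astype(float))
    assert np.allclose(second, cs2 * np.eye(2))


class TestEquilibrium:
    def test_rest_state_equals_weights(self, unit_spec):
        g = equilibrium(1.0, np.zeros(2), unit_spec)
        assert np.allclose(g, W)

    @pytest.mark.parametrize("rho,u", [(1.0, (0.0, 0.0)), (1.2, (0.05, -0.03)),
                                       (0.7, (0.1, 0.0))])
    def test_zeroth_and_first_moments(self, unit_spec, rho, u):
        g = equilibrium(rho, np.asarray(u), unit_spec)
        assert g.sum() == pytest.approx(rho, rel=1e-14)
        # first moment recovers rho * u for the second-order equilibrium
        assert np.allclose(g @ E, rho * np.asarray(u), atol=1e-14)

    def test_rejects_bad_inputs(self, unit_spec):
        with pytest.raises(ValueError):
            equilibrium(-1.0, np.zeros(2), unit_spec)
        with pytest.raises(ValueError):
            equilibrium(1.0, np.array([np.nan, 0.0]), unit_spec)


class TestGuoSource:
    def test_zero_force_is_zero(self, unit_spec):
        G = guo_source(np.array([0.01, 0.0]), np.zeros(2), 1.0, unit_spec)
        assert np.allclose(G, 0.0)

    def test_density_moment_vanishes_at_rest(self, unit_spec):
        G = guo_source(np.zeros(2), np.array([1e-5, 2e-5]), 0.8, unit_spec)
        assert G.sum() == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("tau", [0.6, 1.0, 2.5])
    def test_momentum_moment_carries_prefactor(self, unit_spec, tau):
        # brute-force sum over the nine directions: sum_i G_i e_i = (1 - 1/(2 tau)) f
        f = np.array([1e-5, -3e-6])
        G = guo_source(np.zeros(2), f, tau, unit_spec)
        assert np.allclose(G @ E, (1 - 0.5 / tau) * f, rtol=1e-12)

    def test_unstable_tau_rejected(self, unit_spec):
        with pytest.raises(ValueError):
            guo_source(np.zeros(2), np.zeros(2), 0.5, unit_spec)


class TestCollideStream:
    def test_global_equilibrium_is_fixed_point(self):
        spec = LatticeSpec(9, 7)
        for tau in (0.6, 1.3):
            f = FluidField.uniform(spec, rho=1.0, tau=tau)
            g0 = f.g.copy()
            for _ in range(5):
                collide_stream(f, spec)
                macroscopic(f, spec)
            assert np.allclose(f.g, g0, atol=1e-15)

    def test_single_node_perturbation_spreads_by_weights(self):
        # tau = 1 collision relaxes fully to equilibrium; one streaming step
        # moves the equilibrium fractions w_i onto the 9 neighbours
        spec = LatticeSpec(9, 9)
        f = FluidField.uniform(spec, tau=1.0)
        eps = 1e-6
        f.g[:, 4, 4] += eps * W          # an equilibrium-shaped density bump
        f.rho[4, 4] += eps
        collide_stream(f, spec)
        gp = f.g - equilibrium(np.ones((9, 9)), np.zeros((2, 9, 9)), spec)
        for k in range(9):
            j, i = 4 + E[k, 1], 4 + E[k, 0]
            assert gp[k, j, i] == pytest.approx(eps * W[k], rel=1e-6)

    def test_nan_detection_aborts(self):
        spec = LatticeSpec(6, 6)
        f = FluidField.uniform(spec, tau=0.8)
        f.g[3, 2, 2] = np.nan
        with pytest.raises(FloatingPointError):
            collide_stream(f, spec)

    @pytest.mark.parametrize("tau", [0.6, 1.0, 1.5])
    def test_shear_wave_decay_matches_viscosity(self, tau):
        # nu measured from the decay of u_x = A sin(2 pi y / ny) vs cs^2 (tau - 1/2)
        spec = LatticeSpec(8, 64)
        f = FluidField.uniform(spec, tau=tau)
        u, info = make_analytic_field("shear_wave", 64, 8, A=1e-3)
        f.u[:] = u
        f.g = equilibrium(f.rho, f.u, spec)
        amps = []
        for _ in range(400):
            collide_stream(f, spec)
            macroscopic(f, spec)
            amps.append(np.abs(f.u[0]).max())
        rate = -np.polyfit(np.arange(400), np.log(amps), 1)[0]
        nu_measured = rate / info["k"] ** 2
        assert nu_measured == pytest.approx((tau - 0.5) / 3.0, rel=0.01)


def test_mass_conservation_periodic_noslip_slip():
    # |sum rho(t) - sum rho(0)| / sum rho(0) < 1e-12 over 1000 unforced steps
    spec = LatticeSpec(24, 16)
    f = FluidField.uniform(spec, tau=0.9)
    rng = np.random.default_rng(7)
    f.u[:] = 1e-3 * rng.standard_normal((2, 16, 24))
    f.g = equilibrium(f.rho, f.u, spec)
    bc = BoundarySpec(bottom="noslip", top="slip")
    m0 = f.g.sum()
    for _ in range(1000):
        collide_stream(f, spec, bc)
        macroscopic(f, spec)
    assert abs(f.g.sum() - m0) / m0 < 1e-12


def test_macroscopic_half_force_correction():
    spec = LatticeSpec(5, 5)
    f = FluidField.uniform(spec, tau=1.0)
    f.f_body[0] += 1e-4
    macroscopic(f, spec)
    assert np.allclose(f.u[0], 5e-5, rtol=1e-12)
    assert np.allclose(f.p, spec.cs ** 2 * f.rho)


def test_body_force_half_poiseuille_slip_top():
    """Bottom no-slip, top slip, uniform force: analytic half-channel profile.

    The slip top behaves like the symmetry plane of a channel of double
    height: u(y) = (f/2 nu) y (2H - y) with walls at y=0 (H = ny).
    """
    ny, nx = 32, 6
    spec = LatticeSpec(nx, ny)
    tau = 0.9
    nu = (tau - 0.5) / 3
    fdrive = 1e-6
    f = FluidField.uniform(spec, tau=tau)
    bc = BoundarySpec(bottom="noslip", top="slip")
    for _ in range(20000):
        f.f_body[0] = fdrive
        collide_stream(f, spec, bc)
        macroscopic(f, spec)
    y = np.arange(ny) + 0.5
    H = float(ny)
    ref = fdrive / (2 * nu) * y * (2 * H - y)
    err = np.abs(f.u[0][:, 0] - ref).max() / ref.max()
    assert err < 0.01


def test_inlet_outflow_preserves_developed_profile():
    """A parabolic inlet through a short channel stays parabolic at outflow."""
    ny, nx = 21, 40
    spec = LatticeSpec(nx, ny)
    tau = 0.8
    u_max = 0.01
    y = np.arange(ny, dtype=float)
    Ly = float(ny - 1)
    prof = 4 * u_max * y * (Ly - y) / Ly ** 2
    u_in = np.zeros((2, ny))
    u_in[0] = prof
    bc = BoundarySpec(bottom="noslip_neq", top="noslip_neq", left="inlet",
                      right="outflow", inlet_profile=u_in)
    f = FluidField.uniform(spec, tau=tau)
    f.u[0] = prof[:, None] * np.ones((1, nx))
    f.g = equilibrium(f.rho, f.u, spec)
    for _ in range(8000):
        collide_stream(f, spec, bc)
        macroscopic(f, spec)
    mid = f.u[0][:, nx // 2]
    assert np.abs(mid - prof).max() / u_max < 0.01


def test_uniform_field_invariant_under_periodic_boundaries(unit_spec):
    f = FluidField.uniform(unit_spec, tau=0.7)
    g0 = f.g.copy()
    apply_boundaries(f, BoundarySpec(), unit_spec)
    assert np.array_equal(f.g, g0)


def test_boundary_spec_validation():
    with pytest.raises(ValueError):
        BoundarySpec(bottom="periodic", top="noslip")
    with pytest.raises(ValueError):
        BoundarySpec(left="inlet", right="outflow")  # missing profile
    with pytest.raises(ValueError):
        BoundarySpec(bottom="weird", top="weird")
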