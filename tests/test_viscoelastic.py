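"""Oldroyd-B stress transport, strain rate, stress force, layer map."""

import numpy as np
import pytest

from ciliaflow.fibers import Fiber
from ciliaflow.fixtures import make_analytic_field, random_smooth_field
from ciliaflow.viscoelastic import (LayerMap, StressField, advance_elastic_stress,
                                    elastic_force_density, newtonian_stress,
                                    strain_rate, update_layer_map)


class TestStrainRate:
    def test_uniform_flow_has_zero_strain_rate(self):
        u, _ = make_analytic_field("uniform", 12, 10, c=(0.08, -0.02))
        assert np.allclose(strain_rate(u), 0.0)

    def test_simple_shear_gives_half_gamma_offdiagonal(self):
        gdot = 0.01
        u, _ = make_analytic_field("shear", 16, 8, gdot=gdot)
        D = strain_rate(u)
        assert np.allclose(D[..., 0, 1], gdot / 2, atol=1e-14)
        assert np.allclose(D[..., 0, 0], 0.0, atol=1e-14)
        assert np.allclose(D[..., 1, 1], 0.0, atol=1e-14)

    def test_random_smooth_field_matches_analytic_gradient(self):
        u, L = random_smooth_field(48, 64, seed=3)
        D = strain_rate(u)
        D_exact = 0.5 * (L + np.transpose(L, (1, 0, 2, 3)))
        # centered differences: O(dx^2) on the interior rows
        interior = slice(2, -2)
        err = np.abs(D[interior, :, 0, 1] - D_exact[0, 1][interior])
        assert err.max() < 2e-2 * max(np.abs(D_exact[0, 1]).max(), 1e-12)


def test_newtonian_stress_is_linear_in_viscosity():
    u, info = make_analytic_field("shear", 10, 8, gdot=0.02)
    D = strain_rate(u)
    s1 = newtonian_stress(D, 0.9)
    assert np.allclose(s1[..., 0, 1], 0.9 * info["gdot"], atol=1e-14)
    assert np.allclose(newtonian_stress(D, 1.8), 2 * s1)
    assert np.allclose(newtonian_stress(0 * D, 0.9), 0.0)


class TestStressTransport:
    def test_quiescent_relaxation_is_exponential(self):
        lam = 200.0
        stress = StressField.zeros((10, 12), lam, eta_e=0.1)
        stress.sxx[:] = 0.5
        stress.sxy[:] = -0.2
        u = np.zeros((2, 10, 12))
        ind = np.ones((10, 12))
        nsteps = 400
        for _ in range(nsteps):
            advance_elastic_stress(stress, u, ind)
        expected = 0.5 / (1 + 1 / lam) ** nsteps   # implicit discrete decay
        assert np.allclose(stress.sxx, expected, rtol=1e-12)
        assert np.allclose(stress.sxx, 0.5 * np.exp(-nsteps / lam), rtol=6e-3)

    @pytest.mark.parametrize("lam,gdot", [(50.0, 1e-3), (2000.0, 1e-3)],
                             ids=["We~0.01", "We~1"])
    def test_steady_simple_shear_recovers_ucm_stresses(self, lam, gdot):
        """sigma_xy = eta_E gdot and N1 = 2 eta_E lam gdot^2 at steady state."""
        eta_e = 0.1
        ny, nx = 24, 8
        u, _ = make_analytic_field("shear", ny, nx, gdot=gdot)
        stress = StressField.zeros((ny, nx), lam, eta_e)
        ind = np.ones((ny, nx))
        for _ in range(int(12 * lam)):
            advance_elastic_stress(stress, u, ind, extrapolate_wall_rows=1)
        mid = (slice(4, -4), slice(None))
        assert np.allclose(stress.sxy[mid], eta_e * gdot, rtol=0.01)
        n1 = stress.sxx[mid] - stress.syy[mid]
        assert np.allclose(n1, 2 * eta_e * lam * gdot ** 2, rtol=0.01)

    def test_symmetry_is_structural(self):
        # the tensor is stored as (sxx, sxy, syy): symmetric by construction
        stress = StressField.zeros((4, 4), 10.0, 0.1)
        t = stress.as_tensor()
        assert np.array_equal(t[..., 0, 1], t[..., 1, 0])

    def test_cfl_violation_aborts(self):
        stress = StressField.zeros((6, 6), 10.0, 0.1)
        u = np.ones((2, 6, 6)) * 1.5
        with pytest.raises(FloatingPointError):
            advance_elastic_stress(stress, u, np.ones((6, 6)))


class TestElasticForce:
    def test_homogeneous_stress_exerts_no_force(self):
        stress = StressField.zeros((10, 12), 10.0, 0.1)
        stress.sxx[:] = 0.7
        stress.syy[:] = -0.3
        f = elastic_force_density(stress, np.ones((10, 12)))
        assert np.allclose(f[:, 1:-1, :], 0.0, atol=1e-14)

    def test_linear_sxx_gives_constant_force(self):
        ny, nx = 8, 16
        stress = StressField.zeros((ny, nx), 10.0, 0.1)
        a = 0.01
        stress.sxx[:] = a * np.arange(nx)[None, :]
        f = elastic_force_density(stress, np.ones((ny, nx)))
        # interior columns (the x-gradient wraps at the periodic seam)
        assert np.allclose(f[0][:, 2:-2], a, atol=1e-13)
        assert np.allclose(f[1], 0.0, atol=1e-13)

    def test_sinusoidal_shear_stress_matches_analytic_divergence(self):
        ny, nx = 48, 8
        stress = StressField.zeros((ny, nx), 10.0, 0.1)
        k = 2 * np.pi / ny
        y = np.arange(ny)
        stress.sxy[:] = np.sin(k * y)[:, None]
        f = elastic_force_density(stress, np.ones((ny, nx)))
        expected = k * np.cos(k * y)
        err = np.abs(f[0][2:-2, 0] - expected[2:-2]).max()
        assert err < k ** 2  # O(dx^2) of the centered stencil

    def test_total_momentum_is_conserved_for_interior_stress(self, rng):
        # stress supported away from the walls: the divergence telescopes to
        # zero total force (momentum goes only where stress gradients live)
        ny, nx = 16, 20
        stress = StressField.zeros((ny, nx), 10.0, 0.1)
        stress.sxx[3:-3] = rng.standard_normal((ny - 6, nx)) * 0.01
        stress.sxy[3:-3] = rng.standard_normal((ny - 6, nx)) * 0.01
        ind = np.ones((ny, nx))
        f = elastic_force_density(stress, ind)
        assert f[0].sum() == pytest.approx(0.0, abs=1e-12)
        assert f[1].sum() == pytest.approx(0.0, abs=1e-12)


class TestLayerMap:
    def _membrane(self, nx, h):
        X = np.column_stack([np.arange(float(nx)), np.asarray(h, float)])
        return Fiber(X=X, role="membrane", period_x=float(nx))

    def test_flat_membrane_partitions_the_channel(self):
        mem = self._membrane(16, np.full(16, 7.5))
        layer = update_layer_map(mem, (20, 16), nu_pcl=0.05, nu_ml=2.0)
        assert np.all(layer.indicator[int(np.ceil(7.5 + 2.0)):, :] == 1.0)
        assert np.all(layer.indicator[: int(7.5 - 2.0), :] == 0.0)
        assert np.all(np.diff(layer.indicator, axis=0) >= -1e-12)
        assert np.allclose(layer.viscosity[0], 0.05)
        assert np.allclose(layer.viscosity[-1], 2.0)

    def test_raising_the_membrane_shifts_the_indicator(self):
        m1 = self._membrane(12, np.full(12, 6.0))
        m2 = self._membrane(12, np.full(12, 9.0))
        l1 = update_layer_map(m1, (24, 12), 0.05, 2.0)
        l2 = update_layer_map(m2, (24, 12), 0.05, 2.0)
        assert np.allclose(l2.indicator[3:], l1.indicator[:-3])

    def test_sinusoidal_membrane_area_matches_quadrature(self):
        nx, ny = 64, 40
        x = np.arange(nx)
        h = 20.0 + 3.0 * np.sin(2 * np.pi * x / nx)
        mem = self._membrane(nx, h)
        layer = update_layer_map(mem, (ny, nx), 0.05, 2.0)
        area = layer.indicator.sum()
        # analytic area above the curve: each column contributes the row
        # count above h_i (rows at integer y, half a cell at each end)
        exact = sum((ny - 1) - hi + 0.5 for hi in h)
        assert area == pytest.approx(exact, rel=0.02)

    def test_tau_field_respects_solvent_split(self):
        mem = self._membrane(8, np.full(8, 5.0))
        layer = update_layer_map(mem, (16, 8), nu_pcl=0.05, nu_ml=2.0)
        tau = layer.tau(rv=0.975)
        assert tau[0, 0] == pytest.approx(0.5 + 3 * 0.05)
        assert tau[-1, 0] == pytest.approx(0.5 + 3 * 0.975 * 2.0)

    def test_conformation_conversion_at_rest_is_identity(self):
        stress = StressField.zeros((4, 4), 10.0, 0.1)
        assert np.allclose(stress.conformation_xx(), 1.0)
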