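"""Node-spring fiber mechanics: tension, bending, driving, conservation."""

import numpy as np
import pytest

from ciliaflow.fibers import (Fiber, VirtualFiber, bending_energy, bending_force,
                              bending_matrix, driving_force, stretching_force,
                              total_fiber_force)
from ciliaflow.fixtures import make_fiber_shape


class TestStretching:
    def test_resting_straight_fiber_is_force_free(self):
        fiber, _ = make_fiber_shape("straight", 15)
        assert np.allclose(stretching_force(fiber), 0.0)

    def test_uniform_stretch_loads_only_the_ends(self):
        eps = 0.01
        fiber, info = make_fiber_shape("stretched", 15, eps=eps, Ks=2.0)
        F = stretching_force(fiber)
        # constant tension: interior nodes balanced, ends pulled inward
        assert np.allclose(F[1:-1], 0.0, atol=1e-13)
        assert F[0, 1] == pytest.approx(info["tension"], rel=1e-10)
        assert F[-1, 1] == pytest.approx(-info["tension"], rel=1e-10)

    def test_internal_forces_sum_to_zero(self, rng):
        X = np.column_stack([rng.normal(0, 0.3, 20), np.arange(20.0)])
        fiber = Fiber(X=X, Ks=2.0, Kb=1.0)
        assert np.allclose(stretching_force(fiber).sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(bending_force(fiber).sum(axis=0), 0.0, atol=1e-12)

    def test_coincident_nodes_rejected(self):
        X = np.zeros((6, 2))
        X[:, 1] = [0, 1, 1, 2, 3, 4]
        with pytest.raises(ValueError):
            stretching_force(Fiber(X=X))


class TestBending:
    @pytest.mark.parametrize("tilt", [0.0, 0.4])
    def test_straight_fiber_has_no_bending_force(self, tilt):
        s = np.arange(12.0)
        X = np.column_stack([s * np.sin(tilt), s * np.cos(tilt)])
        assert np.allclose(bending_force(Fiber(X=X)), 0.0, atol=1e-12)

    def test_quadratic_arc_interior_force_free(self):
        s = np.arange(20.0)
        X = np.column_stack([0.003 * s ** 2, s])
        F = bending_force(Fiber(X=X))
        # fourth difference of a quadratic vanishes away from the free ends
        assert np.allclose(F[2:-2], 0.0, atol=1e-12)

    def test_sinusoid_matches_analytic_fourth_derivative(self):
        fiber, info = make_fiber_shape("sinusoid", 81, a=0.01,
                                       k=2 * np.pi / 20, Kb=1.0)
        F = bending_force(fiber)
        interior = slice(4, -4)
        expected = info["bend_force_x"][interior]
        # restoring force -Kb a k^4 sin(ks) to O(ds^2) in the stencil
        assert np.allclose(F[interior, 0], expected,
                           atol=0.05 * np.abs(expected).max())

    def test_force_descends_bending_energy(self, rng):
        X = np.column_stack([0.2 * rng.standard_normal(15), np.arange(15.0)])
        fiber = Fiber(X=X)
        e0 = bending_energy(fiber)
        F = bending_force(fiber)
        fiber.X = fiber.X + 1e-3 * F
        assert bending_energy(fiber) < e0

    def test_bending_matrix_matches_kernel_force(self, rng):
        X = np.column_stack([0.1 * rng.standard_normal(12), np.arange(12.0)])
        fiber = Fiber(X=X)
        B = bending_matrix(12, fiber.Kb, fiber.rest_ds)
        assert np.allclose(B @ X, bending_force(fiber), atol=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            Fiber(X=np.column_stack([np.zeros(4), np.arange(4.0)]))


class TestDriving:
    def test_no_force_on_target_posture(self):
        fiber, _ = make_fiber_shape("straight", 10)
        virt = VirtualFiber(Y=fiber.X.copy())
        assert np.allclose(driving_force(fiber, virt), 0.0)

    def test_uniform_displacement_gives_uniform_spring_force(self):
        fiber, _ = make_fiber_shape("straight", 10)
        virt = VirtualFiber(Y=fiber.X + [0.2, -0.1], Ksl=1.0)
        F = driving_force(fiber, virt)
        assert np.allclose(F, [0.2, -0.1])

    def test_node_count_mismatch_rejected(self):
        fiber, _ = make_fiber_shape("straight", 10)
        with pytest.raises(ValueError):
            driving_force(fiber, VirtualFiber(Y=np.zeros((8, 2))))

    def test_membrane_is_never_driven(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        mem = Fiber(X=X, role="membrane", period_x=10.0)
        with pytest.raises(ValueError):
            total_fiber_force(mem, VirtualFiber(Y=X.copy()))

    def test_resting_cilium_on_target_is_globally_force_free(self):
        fiber, _ = make_fiber_shape("straight", 12)
        virt = VirtualFiber(Y=fiber.X.copy())
        assert np.allclose(total_fiber_force(fiber, virt), 0.0, atol=1e-12)


class TestMembrane:
    def test_flat_periodic_membrane_is_force_free(self):
        X = np.column_stack([np.arange(24.0), np.full(24, 5.0)])
        mem = Fiber(X=X, role="membrane", period_x=24.0)
        assert np.allclose(total_fiber_force(mem), 0.0, atol=1e-12)

    def test_periodic_forces_sum_to_zero(self, rng):
        X = np.column_stack([np.arange(24.0),
                             5.0 + 0.3 * np.sin(2 * np.pi * np.arange(24) / 24)])
        mem = Fiber(X=X, role="membrane", period_x=24.0)
        F = total_fiber_force(mem)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)
        assert np.abs(F).max() > 0  # curved membrane is loaded

    def test_strain_accounts_for_the_wrap_segment(self):
        X = np.column_stack([np.arange(10.0) * 1.02, np.zeros(10)])
        mem = Fiber(X=X, role="membrane", period_x=10.2)
        assert mem.max_strain() == pytest.approx(0.02, abs=1e-9)
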