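"""Node-spring mechanics of flexible fibers (cilia and the dividing membrane).

A fiber is an ordered chain of Lagrangian nodes.  Its internal force density
(per unit arclength) combines

* stretching, ``F_s = d/ds [ K_s (|dX/ds| - 1) t_hat ]`` — Hookean tension
  along the local tangent, resisting deviation from the natural segment
  length;
* bending, ``F_b = -K_b d^4 X / ds^4`` — the variational derivative of the
  discrete bending energy ``(K_b/2) \\int |X''|^2 ds``, which builds the
  moment-free / shear-free conditions ``X'' = X''' = 0`` into both free ends
  automatically (membrane fibers instead close periodically in x);
* an optional penalty driving force ``F_c = K_sl (Y - X)`` toward a
  prescribed virtual-fiber posture Y (cilia only).

Cilium roots are position-clamped to the bottom wall; the clamp is applied
by the advection step, not through a force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

__all__ = ["Fiber", "VirtualFiber", "stretching_force", "bending_force",
           "driving_force", "total_fiber_force", "bending_energy",
           "bending_matrix", "implicit_fiber_solver"]


@dataclass
class Fiber:
    """Ordered chain of nodes with spring/bending parameters.

    ``role`` is ``"cilium"`` (open, root anchored) or ``"membrane"`` (closed
    periodically in x over a channel of length ``period_x``; node
    x-coordinates are kept unwrapped).
    """

    X: np.ndarray                 # (n, 2) node positions, lattice units
    rest_ds: float = 1.0
    Ks: float = 2.0
    Kb: float = 1.0
    role: str = "cilium"
    anchor: np.ndarray | None = None   # clamped root position (cilia)
    period_x: float | None = None      # channel length (membrane)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ValueError("X must be (n, 2)")
        if self.X.shape[0] < 5:
            raise ValueError("fiber needs at least 5 nodes")
        if self.role not in ("cilium", "membrane"):
            raise ValueError("role must be 'cilium' or 'membrane'")
        if self.role == "membrane" and self.period_x is None:
            raise ValueError("membrane fiber needs period_x")
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    def segment_lengths(self) -> np.ndarray:
        d = np.diff(self.X, axis=0)
        ell = np.hypot(d[:, 0], d[:, 1])
        if self.role == "membrane":
            dx = self.X[0, 0] + self.period_x - self.X[-1, 0]
            dy = self.X[0, 1] - self.X[-1, 1]
            ell = np.append(ell, np.hypot(dx, dy))
        return ell

    def max_strain(self) -> float:
        """Largest relative segment stretch | l/ds - 1 |."""
        return float(np.max(np.abs(self.segment_lengths() / self.rest_ds - 1.0)))


@dataclass
class VirtualFiber:
    """Prescribed-motion ghost fiber that drags a real fiber via penalty springs."""

    Y: np.ndarray          # (n, 2) current virtual posture
    Ksl: float = 1.0

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)


def _internal_forces(fiber: Fiber, ks: float, kb: float) -> np.ndarray:
    if np.any(fiber.segment_lengths() < 1e-12):
        raise ValueError("coincident adjacent fiber nodes")
    F = np.empty_like(fiber.X)
    if fiber.role == "membrane":
        K.closed_fiber_forces(fiber.X, ks, kb, fiber.rest_ds,
                              float(fiber.period_x), F)
    else:
        K.open_fiber_forces(fiber.X, ks, kb, fiber.rest_ds, F)
    return F


def stretching_force(fiber: Fiber) -> np.ndarray:
    """Tension force density (per unit length) at each node."""
    return _internal_forces(fiber, fiber.Ks, 0.0)


def bending_force(fiber: Fiber) -> np.ndarray:
    """Bending force density -K_b X'''' with natural free-end closure."""
    return _internal_forces(fiber, 0.0, fiber.Kb)


def driving_force(fiber: Fiber, virtual: VirtualFiber) -> np.ndarray:
    """Penalty spring force K_sl (Y - X) toward the virtual posture."""
    if virtual.Y.shape != fiber.X.shape:
        raise ValueError("virtual fiber node count must match the driven fiber")
    return virtual.Ksl * (virtual.Y - fiber.X)


def total_fiber_force(fiber: Fiber, virtual: VirtualFiber | None = None) -> np.ndarray:
    """F = F_s + F_b (+ F_c for a driven cilium).

    This is the Lagrangian force density handed to the IB spreading step;
    the fluid receives it directly (the fiber is massless, so the force the
    springs exert on the node is transmitted to the fluid unchanged).
    """
    F = _internal_forces(fiber, fiber.Ks, fiber.Kb)
    if virtual is not None:
        if fiber.role == "membrane":
            raise ValueError("membrane fibers are not driven")
        F += driving_force(fiber, virtual)
    return F


def bending_energy(fiber: Fiber) -> float:
    """Discrete bending energy (K_b/2) sum |second difference|^2 / ds^3."""
    X = fiber.X
    if fiber.role == "membrane":
        Xp = np.vstack([X[-1] - [fiber.period_x, 0.0], X, X[0] + [fiber.period_x, 0.0]])
        k = Xp[:-2] - 2 * Xp[1:-1] + Xp[2:]
    else:
        k = X[:-2] - 2 * X[1:-1] + X[2:]
    return float(0.5 * fiber.Kb * np.sum(k ** 2) / fiber.rest_ds ** 3)


def bending_matrix(n: int, kb: float, ds: float = 1.0,
                   periodic: bool = False) -> np.ndarray:
    """Linear operator of the discrete bending force: F = B X.

    ``B = -(kb/ds^4) D2^T D2`` with D2 the second-difference map evaluated
    at interior nodes (natural free ends) or cyclically (periodic fibers).
    """
    if periodic:
        rows = n
        D2 = np.zeros((rows, n))
        for c in range(n):
            D2[c, (c - 1) % n] = 1.0
            D2[c, c] = -2.0
            D2[c, (c + 1) % n] = 1.0
    else:
        rows = n - 2
        D2 = np.zeros((rows, n))
        for c in range(1, n - 1):
            D2[c - 1, c - 1] = 1.0
            D2[c - 1, c] = -2.0
            D2[c - 1, c + 1] = 1.0
    return -(kb / ds ** 4) * (D2.T @ D2)


def stretch_laplacian(n: int, ks: float, ds: float = 1.0,
                      periodic: bool = False) -> np.ndarray:
    """Linearized stretching operator of the spring chain.

    For longitudinal displacements the Hookean chain force is exactly
    ``F = (ks/ds^2) (X_{i-1} - 2 X_i + X_{i+1})`` (graph Laplacian form);
    it is the stiffness that the IMEX split stabilizes.
    """
    L = np.zeros((n, n))
    for i in range(n):
        for jn in ((i - 1), (i + 1)):
            j = jn % n if periodic else jn
            if 0 <= j < n:
                L[i, j] += 1.0
                L[i, i] -= 1.0
    return (ks / ds ** 2) * L


def implicit_fiber_solver(n: int, kb: float, ksl: float, mobility: float,
                          ds: float = 1.0, ks: float = 0.0,
                          periodic: bool = False,
                          clamp_root: bool = False) -> np.ndarray:
    """Prefactored IMEX matrix M = (I - m A)^{-1} for the stiff fiber forces.

    ``A`` collects the linear(ized) stiff operators — bending, the penalty
    spring and the stretching Laplacian — and ``m`` is the effective
    per-step mobility of a Lagrangian node (the velocity a unit force
    density produces within one step through the spreading/interpolation
    kernel pair, about ``sum phi^2 / rho``).  One IMEX step evaluates the
    full nonlinear force ``F(X)`` exactly and spreads

        F_impl = F(X) + A (X~ - X),   (I - m A)(X~ - X) = m F(X),

    i.e. ``F_impl = (X~ - X)/m`` with ``X~ = X + M m F(X)``.  At a force
    equilibrium ``X~ = X`` and the spread force is exact; away from it the
    stiff modes relax monotonically instead of ringing unstably through the
    explicit fluid coupling.

    ``clamp_root=True`` pins node 0 (it neither moves nor exerts force).
    """
    A = (bending_matrix(n, kb, ds, periodic) + stretch_laplacian(n, ks, ds, periodic)
         - ksl * np.eye(n))
    if clamp_root:
        A[0, :] = 0.0
    return np.linalg.inv(np.eye(n) - mobility * A)
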