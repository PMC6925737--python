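"""D2Q9 lattice-Boltzmann core: BGK collision with Guo body-force coupling.

The solver works in lattice units (dx = dt = 1 by default) on a rectangular
grid indexed ``[j, i]`` = ``[y, x]``.  Distribution functions are stored as an
array of shape ``(9, ny, nx)``.  Physical walls sit half a cell outside the
first/last row of nodes (halfway bounce-back convention), so a channel with
``ny`` rows has hydraulic height ``ny`` lattice units and node ``j`` lies at
``y = j + 1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

__all__ = [
    "E",
    "W",
    "OPP",
    "LatticeSpec",
    "FluidField",
    "BoundarySpec",
    "equilibrium",
    "guo_source",
    "collide_stream",
    "macroscopic",
    "apply_boundaries",
]

#: discrete velocity set (rest, axis, diagonal), shape (9, 2), columns (ex, ey)
E = np.array(
    [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1], [-1, 1], [-1, -1], [1, -1]],
    dtype=np.int64,
)
#: quadrature weights
W = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36])
#: index of the opposite direction
OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64)


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and discretization of the D2Q9 lattice.

    Parameters
    ----------
    nx, ny : int
        Node counts in x and y (each at least 3).
    dx, dt : float
        Lattice spacing and time step.  The production solver always uses
        ``dx = dt = 1``; the general form is kept for unit checks.
    """

    nx: int
    ny: int
    dx: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("lattice needs nx, ny >= 3")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")

    @property
    def cs(self) -> float:
        """Lattice sound speed dx / (sqrt(3) dt)."""
        return self.dx / (np.sqrt(3.0) * self.dt)

    @property
    def c(self) -> float:
        return self.dx / self.dt

    @property
    def e(self) -> np.ndarray:
        return E * self.c

    @property
    def w(self) -> np.ndarray:
        return W


# per-edge boundary kinds understood by apply_boundaries / collide_stream
_EDGE_KINDS_Y = ("periodic", "noslip", "slip", "noslip_neq")
_EDGE_KINDS_X = ("periodic", "inlet", "outflow")
# noslip_neq rows are rebuilt wholesale after streaming (code 0 in-kernel)
_YCODE = {"periodic": 0, "noslip": 1, "slip": 2, "noslip_neq": 0}


@dataclass
class BoundarySpec:
    """Boundary condition per edge.

    ``bottom``/``top`` accept ``periodic | noslip | slip`` and are resolved
    inside the streaming step (bounce-back / specular reflection of the
    post-collision populations).  ``left``/``right`` accept
    ``periodic | inlet | outflow`` and are imposed afterwards with the
    non-equilibrium extrapolation scheme; ``inlet_profile`` gives the imposed
    velocity ``(2, ny)`` on the inlet column.
    """

    bottom: str = "periodic"
    top: str = "periodic"
    left: str = "periodic"
    right: str = "periodic"
    inlet_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bottom not in _EDGE_KINDS_Y or self.top not in _EDGE_KINDS_Y:
            raise ValueError(f"bottom/top must be one of {_EDGE_KINDS_Y}")
        if self.left not in _EDGE_KINDS_X or self.right not in _EDGE_KINDS_X:
            raise ValueError(f"left/right must be one of {_EDGE_KINDS_X}")
        if (self.left == "periodic") != (self.right == "periodic"):
            raise ValueError("periodic x-boundaries must be paired")
        if (self.bottom == "periodic") != (self.top == "periodic"):
            raise ValueError("periodic y-boundaries must be paired")
        if self.left == "inlet" and self.inlet_profile is None:
            raise ValueError("inlet boundary requires inlet_profile")


@dataclass
class FluidField:
    """Distribution functions plus macroscopic moments on one lattice.

    ``tau`` may be a scalar or a per-node array (two-layer runs use a
    spatially varying relaxation time).  ``f_body`` holds the total body-force
    density entering the Guo forcing term.
    """

    spec: LatticeSpec
    g: np.ndarray
    rho: np.ndarray
    u: np.ndarray
    f_body: np.ndarray
    tau: np.ndarray
    _scratch: tuple | None = None

    @classmethod
    def uniform(cls, spec: LatticeSpec, rho: float = 1.0,
                u: tuple[float, float] = (0.0, 0.0), tau: float | np.ndarray = 1.0
                ) -> "FluidField":
        shape = (spec.ny, spec.nx)
        rho_f = np.full(shape, float(rho))
        u_f = np.zeros((2,) + shape)
        u_f[0] += u[0]
        u_f[1] += u[1]
        g = equilibrium(rho_f, u_f, spec)
        tau_f = np.broadcast_to(np.asarray(tau, dtype=float), shape).copy()
        if np.any(tau_f <= 0.5):
            raise ValueError("tau must exceed 0.5 everywhere")
        return cls(spec=spec, g=g, rho=rho_f, u=u_f,
                   f_body=np.zeros((2,) + shape), tau=tau_f)

    @property
    def p(self) -> np.ndarray:
        """Pressure p = cs^2 rho."""
        return self.spec.cs ** 2 * self.rho

    def nu(self) -> np.ndarray:
        """Kinematic viscosity cs^2 (tau - 1/2) dt implied by tau."""
        return self.spec.cs ** 2 * (self.tau - 0.5) * self.spec.dt


def equilibrium(rho, u, spec: LatticeSpec) -> np.ndarray:
    """Second-order equilibrium distribution.

    ``g_i^eq = w_i rho [1 + e.u/cs^2 + ((e.u)^2 - cs^2 |u|^2)/(2 cs^4)]``.
    Accepts scalars or per-node arrays; returns an array with a leading
    9-axis.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite density or velocity")
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    cs2 = spec.cs ** 2
    e = spec.e  # (9, 2)
    ux, uy = u[0], u[1]
    usq = ux * ux + uy * uy
    out = np.empty((9,) + np.shape(rho))
    for i in range(9):
        eu = e[i, 0] * ux + e[i, 1] * uy
        out[i] = W[i] * rho * (1.0 + eu / cs2 + eu * eu / (2 * cs2 * cs2)
                               - usq / (2 * cs2))
    return out


def guo_source(u, f, tau, spec: LatticeSpec) -> np.ndarray:
    """Guo forcing term ``G_i = (1 - 1/(2 tau)) w_i [(e-u)/cs^2 + (e.u)e/cs^4] . f``."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0.5):
        raise ValueError("tau must exceed 0.5 (unstable viscosity)")
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    cs2 = spec.cs ** 2
    e = spec.e
    pref = 1.0 - 0.5 / tau
    out = np.empty((9,) + np.shape(u[0]))
    for i in range(9):
        eu = e[i, 0] * u[0] + e[i, 1] * u[1]
        bx = (e[i, 0] - u[0]) / cs2 + eu * e[i, 0] / cs2 ** 2
        by = (e[i, 1] - u[1]) / cs2 + eu * e[i, 1] / cs2 ** 2
        out[i] = pref * W[i] * (bx * f[0] + by * f[1])
    return out


def collide_stream(field: FluidField, spec: LatticeSpec | None = None,
                   bc: BoundarySpec | None = None, check: bool = True) -> FluidField:
    """One BGK collision + streaming step (in place on ``field.g``).

    Collides with the local ``tau`` and Guo source built from ``field.u`` and
    ``field.f_body``, then streams with periodic wrap; the y-edge conditions
    of ``bc`` (bounce-back / specular) are folded into the streaming of the
    boundary rows.  Macroscopic moments are *not* refreshed here.
    """
    spec = spec or field.spec
    bc = bc or BoundarySpec()
    if spec.dx != 1.0 or spec.dt != 1.0:
        raise ValueError("collide_stream runs in unit lattice spacing/steps")
    if field._scratch is None or field._scratch[0].shape != field.g.shape:
        field._scratch = (np.empty_like(field.g), np.zeros_like(field.g))
    gn, tmp = field._scratch
    K.collide_stream_kernel(
        field.g, gn, tmp, field.rho, field.u[0], field.u[1],
        field.f_body[0], field.f_body[1], field.tau,
        _YCODE[bc.bottom], _YCODE[bc.top],
    )
    if check and not np.all(np.isfinite(gn)):
        bad = np.argwhere(~np.isfinite(gn))[0]
        raise FloatingPointError(
            f"NaN/Inf in distribution i={bad[0]} at node (y={bad[1]}, x={bad[2]})")
    field._scratch = (field.g, tmp)
    field.g = gn
    if bc.bottom == "noslip_neq" or bc.top == "noslip_neq":
        _neq_wall_rows(field, bc, spec)
    if bc.left != "periodic":
        apply_boundaries(field, bc, spec)
    return field


def _neq_wall_rows(field: FluidField, bc: BoundarySpec, spec: LatticeSpec) -> None:
    """Resting-wall rows imposed by non-equilibrium extrapolation.

    The wall coincides with the node row (not the halfway plane):
    ``g_wall = g_eq(rho_nb, 0) + (g_nb - g_eq(rho_nb, u_nb))``.
    """
    g = field.g
    zeros = None
    for edge, kind in (("bottom", bc.bottom), ("top", bc.top)):
        if kind != "noslip_neq":
            continue
        row = 0 if edge == "bottom" else spec.ny - 1
        nb = 1 if edge == "bottom" else spec.ny - 2
        rho_nb = g[:, nb, :].sum(axis=0)
        mom = np.tensordot(g[:, nb, :], E.astype(float), axes=(0, 0)).T
        u_nb = mom / rho_nb
        if zeros is None:
            zeros = np.zeros_like(u_nb)
        geq_nb = equilibrium(rho_nb, u_nb, spec)
        geq_bc = equilibrium(rho_nb, zeros, spec)
        g[:, row, :] = geq_bc + (g[:, nb, :] - geq_nb)


def macroscopic(field: FluidField, spec: LatticeSpec | None = None):
    """Moments of the post-streaming distributions with Guo half-force shift.

    ``rho = sum_i g_i``; ``u = (sum_i g_i e_i + dt f/2) / rho``; ``p = cs^2 rho``.
    Updates ``field.rho`` and ``field.u`` in place and returns ``(rho, u, p)``.
    """
    spec = spec or field.spec
    bad = K.macroscopic_kernel(field.g, field.rho, field.u[0], field.u[1],
                               field.f_body[0], field.f_body[1])
    if bad:
        raise FloatingPointError(
            "non-positive or non-finite density encountered — blow-up")
    return field.rho, field.u, field.p


def apply_boundaries(field: FluidField, bc: BoundarySpec,
                     spec: LatticeSpec | None = None) -> FluidField:
    """Impose the x-edge (inlet/outflow) conditions by non-equilibrium extrapolation.

    The y-edge conditions are handled inside :func:`collide_stream`; calling
    this with purely periodic ``bc`` is a no-op.  For ``inlet`` the imposed
    velocity profile and the neighbour density are combined as
    ``g = g_eq(rho_nb, u_bc) + (g_nb - g_eq(rho_nb, u_nb))``; ``outflow``
    uses the zero-gradient extrapolated velocity.
    """
    spec = spec or field.spec
    if bc.left == "periodic":
        return field
    g = field.g
    for side, kind in (("left", bc.left), ("right", bc.right)):
        col = 0 if side == "left" else spec.nx - 1
        nb = 1 if side == "left" else spec.nx - 2
        rho_nb = g[:, :, nb].sum(axis=0)
        mom = np.tensordot(g[:, :, nb], E.astype(float), axes=(0, 0)).T  # (2, ny)
        u_nb = mom / rho_nb
        if kind == "inlet":
            u_bc = np.asarray(bc.inlet_profile, dtype=float)
            rho_bc = rho_nb
        else:  # outflow: zero-gradient velocity, density anchored at 1
            u_bc = u_nb
            rho_bc = np.ones_like(rho_nb)
        geq_nb = equilibrium(rho_nb, u_nb, spec)
        geq_bc = equilibrium(rho_bc, u_bc, spec)
        g[:, :, col] = geq_bc + (g[:, :, nb] - geq_nb)
    return field
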