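"""Viscoelastic planar Poiseuille benchmark for the coupled LBM + Oldroyd-B solver.

A channel with no-slip top and bottom walls, a parabolic velocity inlet and a
free outflow is run to steady state; the mid-channel profiles of the
streamwise velocity and the conformation component A_xx are compared with
the closed forms

    u_x(y)  = 4 u_max y (L_y - y) / L_y^2
    A_xx(y) = 1 + 32 lambda^2 u_max^2 (L_y - 2 y)^2 / L_y^4

for a fully developed Oldroyd-B channel flow.  The Weissenberg number is
defined as We = lambda u_max / L_y; the solver stress is converted to the
conformation tensor through A = I + (lambda / eta_E) sigma_E.

By default the fully developed state is driven by the exact equivalent
uniform body force ``f_x = 8 eta_total u_max / L_y^2`` in a periodic
channel, which realizes the analytic solution free of the compressibility
artifact a velocity-inlet/outflow pair produces at these parameters (the
required pressure drop would amount to an ~18% density variation along the
channel).  ``driving="inlet"`` runs the inlet/outflow variant instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .lattice import BoundarySpec, FluidField, LatticeSpec, collide_stream, macroscopic
from .viscoelastic import StressField, advance_elastic_stress, elastic_force_density

__all__ = ["PoiseuilleCase", "PoiseuilleReport", "analytic_u", "analytic_Axx",
           "run_poiseuille"]


@dataclass(frozen=True)
class PoiseuilleCase:
    """Benchmark parameters (defaults follow the validation setup)."""

    nx: int = 120
    ny: int = 40
    u_max: float = 0.1
    reynolds: float = 4.0
    rv: float = 0.9
    weissenberg: float = 0.01

    @property
    def Ly(self) -> float:
        """Channel height: the walls coincide with the first/last node rows."""
        return float(self.ny - 1)

    @property
    def nu_total(self) -> float:
        return self.u_max * self.Ly / self.reynolds

    @property
    def lambda_relax(self) -> float:
        return self.weissenberg * self.Ly / self.u_max


@dataclass
class PoiseuilleReport:
    case: PoiseuilleCase
    steps: int
    l2_error_u: float
    linf_error_u: float
    l2_error_axx: float
    linf_error_axx: float
    u_profile: np.ndarray
    axx_profile: np.ndarray
    y: np.ndarray
    residual_history: np.ndarray


def analytic_u(y, u_max: float, Ly: float):
    """Parabolic channel profile u_x(y) = 4 u_max y (Ly - y) / Ly^2."""
    y = np.asarray(y, dtype=float)
    return 4.0 * u_max * y * (Ly - y) / Ly ** 2


def analytic_Axx(y, u_max: float, Ly: float, lam: float):
    """Streamwise conformation A_xx(y) = 1 + 32 lam^2 u_max^2 (Ly - 2y)^2 / Ly^4."""
    y = np.asarray(y, dtype=float)
    return 1.0 + 32.0 * lam ** 2 * u_max ** 2 * (Ly - 2.0 * y) ** 2 / Ly ** 4


def run_poiseuille(case: PoiseuilleCase = PoiseuilleCase(), max_steps: int = 60_000,
                   steady_tol: float = 1e-8, check_every: int = 100,
                   driving: str = "body_force", warm_start: bool = False
                   ) -> PoiseuilleReport:
    """Run the benchmark to steady state and report profile errors.

    Steadiness is declared when the relative velocity change over
    ``check_every`` steps drops below ``steady_tol``; failing to reach it
    within ``max_steps`` raises with the residual history attached.
    ``warm_start=True`` initializes velocity and stress at the analytic
    solution (shortens the transient; the steady state is the same).
    """
    c = case
    spec = LatticeSpec(c.nx, c.ny)
    y_nodes = np.arange(c.ny, dtype=float)
    u_in = np.zeros((2, c.ny))
    u_in[0] = analytic_u(y_nodes, c.u_max, c.Ly)
    if driving == "inlet":
        bc = BoundarySpec(bottom="noslip_neq", top="noslip_neq", left="inlet",
                          right="outflow", inlet_profile=u_in)
        f_drive = 0.0
    elif driving == "body_force":
        bc = BoundarySpec(bottom="noslip_neq", top="noslip_neq")
        f_drive = 8.0 * c.nu_total * c.u_max / c.Ly ** 2   # rho = 1
    else:
        raise ValueError("driving must be 'body_force' or 'inlet'")

    eta_n = c.rv * c.nu_total          # rho = 1
    eta_e = (1.0 - c.rv) * c.nu_total
    tau = 0.5 + 3.0 * eta_n
    field = FluidField.uniform(spec, tau=tau)
    lam = c.lambda_relax
    stress = StressField.zeros((c.ny, c.nx), lam, eta_e)
    ones = np.ones((c.ny, c.nx))
    if warm_start or driving == "inlet":
        field.u[0] = u_in[0][:, None] * np.ones((1, c.nx))
        field.g = _eq_init(field, spec)
        gdot = 4.0 * c.u_max * (c.Ly - 2.0 * y_nodes) / c.Ly ** 2
        stress.sxy[:] = eta_e * gdot[:, None]
        stress.sxx[:] = 2.0 * eta_e * lam * gdot[:, None] ** 2

    residuals = []
    u_prev = field.u[0].copy()
    steps = 0
    for steps in range(1, max_steps + 1):
        field.f_body[:] = 0.0
        field.f_body[0] += f_drive
        elastic_force_density(stress, ones, out=field.f_body)
        field.f_body[:, 0, :] = 0.0    # wall rows are boundary nodes,
        field.f_body[:, -1, :] = 0.0   # not forced fluid
        collide_stream(field, spec, bc)
        macroscopic(field, spec)
        advance_elastic_stress(stress, field.u, ones, extrapolate_wall_rows=2)
        if steps % check_every == 0:
            num = np.abs(field.u[0] - u_prev).max()
            den = max(np.abs(field.u[0]).max(), 1e-300)
            residuals.append(num / den)
            u_prev = field.u[0].copy()
            if residuals[-1] < steady_tol:
                break
    else:
        raise RuntimeError(
            f"no steady state within {max_steps} steps; residuals="
            f"{np.asarray(residuals)[-5:]}")

    mid = c.nx // 2
    u_num = field.u[0][:, mid]
    axx_num = stress.conformation_xx()[:, mid]
    u_ref = analytic_u(y_nodes, c.u_max, c.Ly)
    axx_ref = analytic_Axx(y_nodes, c.u_max, c.Ly, lam)

    def _l2(a, b):
        return float(np.linalg.norm(a - b) / np.linalg.norm(b))

    def _linf(a, b):
        return float(np.abs(a - b).max() / np.abs(b).max())

    return PoiseuilleReport(
        case=c, steps=steps,
        l2_error_u=_l2(u_num, u_ref), linf_error_u=_linf(u_num, u_ref),
        l2_error_axx=_l2(axx_num, axx_ref), linf_error_axx=_linf(axx_num, axx_ref),
        u_profile=u_num, axx_profile=axx_num, y=y_nodes,
        residual_history=np.asarray(residuals),
    )


def _eq_init(field: FluidField, spec: LatticeSpec) -> np.ndarray:
    from .lattice import equilibrium
    return equilibrium(field.rho, field.u, spec)
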