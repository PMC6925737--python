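"""Oldroyd-B elastic stress of the mucus layer and the two-layer viscosity map.

The mucus stress splits into a Newtonian solvent part ``sigma_N = 2 eta_N D``
handled by the LBM viscosity, and an elastic part ``sigma_E`` obeying the
upper-convected Maxwell law

    sigma_E + lambda * (d/dt + u.grad - L . - . L^T) sigma_E = 2 eta_E D,

advanced explicitly with first-order upwind advection.  The divergence of
``sigma_E`` enters the momentum equation as a body force.  A smoothed
indicator built from the membrane curve distinguishes the viscoelastic mucus
layer (indicator 1) from the Newtonian periciliary liquid (indicator 0); the
LBM relaxation time varies in space so the solvent viscosity jumps across
the membrane by the configured mucus:PCL ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .fibers import Fiber

__all__ = ["StressField", "LayerMap", "strain_rate", "newtonian_stress",
           "advance_elastic_stress", "elastic_force_density", "update_layer_map",
           "membrane_height_profile"]


@dataclass
class LayerMap:
    """Per-node mucus/PCL indicator and total-viscosity map.

    ``indicator`` is 1 in the mucus layer (ML), 0 in the periciliary liquid
    (PCL), with a smooth transition of half-width ``halfwidth`` lattice units
    across the membrane.  ``viscosity`` interpolates linearly between the PCL
    value and the ML total value.
    """

    indicator: np.ndarray
    nu_pcl: float
    nu_ml: float
    halfwidth: float = 2.0

    @property
    def viscosity(self) -> np.ndarray:
        return self.nu_pcl + (self.nu_ml - self.nu_pcl) * self.indicator

    def solvent_viscosity(self, rv: float) -> np.ndarray:
        """LBM (solvent) viscosity: full PCL value, Newtonian fraction rv in ML."""
        return self.nu_pcl + (rv * self.nu_ml - self.nu_pcl) * self.indicator

    def tau(self, rv: float) -> np.ndarray:
        """Relaxation-time field implied by the solvent viscosity (cs^2 = 1/3)."""
        return 0.5 + 3.0 * self.solvent_viscosity(rv)


@dataclass
class StressField:
    """Symmetric elastic stress tensor per node plus the constitutive constants."""

    sxx: np.ndarray
    sxy: np.ndarray
    syy: np.ndarray
    lambda_relax: float
    eta_e: float           # elastic viscosity inside the mucus layer
    eta_n: float = 0.0     # solvent viscosity (bookkeeping; lives in the LBM tau)

    @classmethod
    def zeros(cls, shape, lambda_relax: float, eta_e: float,
              eta_n: float = 0.0) -> "StressField":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape),
                   float(lambda_relax), float(eta_e), float(eta_n))

    def conformation_xx(self) -> np.ndarray:
        """A_xx = 1 + (lambda/eta_E) sigma_E,xx (unit-trace-at-rest convention).

        In the Newtonian limit eta_E = 0 the stress vanishes identically and
        the conformation is the rest state A_xx = 1."""
        if self.eta_e == 0.0:
            return np.ones_like(self.sxx)
        return 1.0 + self.lambda_relax / self.eta_e * self.sxx

    def as_tensor(self) -> np.ndarray:
        out = np.empty(self.sxx.shape + (2, 2))
        out[..., 0, 0] = self.sxx
        out[..., 0, 1] = self.sxy
        out[..., 1, 0] = self.sxy
        out[..., 1, 1] = self.syy
        return out


def strain_rate(u_field: np.ndarray) -> np.ndarray:
    """D = (grad u + grad u^T)/2 by centered differences.

    Periodic in x, one-sided at the y walls.  Returns shape (ny, nx, 2, 2).
    """
    ux, uy = np.asarray(u_field[0], float), np.asarray(u_field[1], float)
    ny, nx = ux.shape
    lxx = np.empty_like(ux); lxy = np.empty_like(ux)
    lyx = np.empty_like(ux); lyy = np.empty_like(ux)
    K.velocity_gradient_kernel(ux, uy, lxx, lxy, lyx, lyy)
    D = np.empty((ny, nx, 2, 2))
    D[..., 0, 0] = lxx
    D[..., 1, 1] = lyy
    D[..., 0, 1] = D[..., 1, 0] = 0.5 * (lxy + lyx)
    return D


def newtonian_stress(D: np.ndarray, eta_n) -> np.ndarray:
    """sigma_N = 2 eta_N D (eta_N scalar or per-node)."""
    eta = np.asarray(eta_n, dtype=float)
    return 2.0 * eta[..., None, None] * D if eta.ndim else 2.0 * eta * D


def advance_elastic_stress(stress: StressField, u_field: np.ndarray,
                           indicator: np.ndarray, dt: float = 1.0,
                           extrapolate_wall_rows: int = 0,
                           kappa: float = 0.0) -> StressField:
    """One explicit upwind step of the UCM transport equation (in place).

    The elastic source ``2 eta_E D`` is weighted by the layer indicator, so
    stress is generated only in the mucus layer; elsewhere it is advected and
    relaxes to zero.  Symmetry is preserved by construction (the three stored
    components are the full tensor).

    ``kappa`` adds the stress diffusivity ``kappa Lap(sigma)`` — the usual
    regularization of the UCM transport (off by default; the two-layer
    simulation enables it).

    ``extrapolate_wall_rows=k`` replaces the stress in the ``k`` rows next to
    each y-wall by quadratic extrapolation from the interior.  This is the
    stress wall condition used when the walls are Dirichlet velocity rows
    (the channel benchmark): the lattice velocity in the slip layer next to
    such rows carries an O((tau-1/2)^2) defect that would otherwise corrupt
    the local shear rate, while the interior stress is clean.
    """
    ux, uy = u_field[0], u_field[1]
    cfl = max(np.abs(ux).max(), np.abs(uy).max()) * dt
    if cfl >= 1.0:
        raise FloatingPointError(f"stress advection CFL violated: max|u| dt = {cfl:.3g}")
    nxx = np.empty_like(stress.sxx)
    nxy = np.empty_like(stress.sxy)
    nyy = np.empty_like(stress.syy)
    K.stress_step_kernel(stress.sxx, stress.sxy, stress.syy, nxx, nxy, nyy,
                         ux, uy, indicator, stress.eta_e, stress.lambda_relax,
                         dt, kappa)
    for comp in (nxx, nxy, nyy):
        for j in range(extrapolate_wall_rows - 1, -1, -1):
            comp[j] = 3.0 * comp[j + 1] - 3.0 * comp[j + 2] + comp[j + 3]
            comp[-1 - j] = (3.0 * comp[-2 - j] - 3.0 * comp[-3 - j]
                            + comp[-4 - j])
    stress.sxx, stress.sxy, stress.syy = nxx, nxy, nyy
    return stress


def elastic_force_density(stress: StressField, indicator: np.ndarray,
                          out: np.ndarray | None = None) -> np.ndarray:
    """Body-force density f = div(indicator * sigma_E), accumulated into ``out``.

    Tapering the stress with the indicator before taking the divergence keeps
    the total momentum injected by the elastic force zero over the periodic
    domain while confining it to the mucus layer.
    """
    if out is None:
        out = np.zeros((2,) + stress.sxx.shape)
    K.stress_divergence_kernel(stress.sxx, stress.sxy, stress.syy,
                               np.asarray(indicator, float), out[0], out[1])
    return out


def membrane_height_profile(membrane: Fiber, nx: int) -> np.ndarray:
    """Membrane height h(x) sampled at the lattice columns x = 0..nx-1.

    The membrane nodes keep unwrapped x-coordinates; they are folded into
    [0, nx), sorted, and linearly interpolated.  A fold-over (non-single-
    valued curve) aborts with a geometry error.
    """
    x = np.mod(membrane.X[:, 0], nx)
    y = membrane.X[:, 1]
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if np.any(np.diff(xs) <= 1e-12):
        # two nodes in the same column: tolerate by averaging, abort on folds
        xs, idx = np.unique(xs, return_index=True)
        ys = ys[idx]
    if xs.size < 4:
        raise ValueError("membrane folded: height profile undefined")
    return np.interp(np.arange(nx, dtype=float), xs, ys,
                     period=float(nx))


def update_layer_map(membrane: Fiber, lattice_shape, nu_pcl: float, nu_ml: float,
                     halfwidth: float = 2.0, layer: LayerMap | None = None
                     ) -> LayerMap:
    """Rebuild the indicator / viscosity map from the current membrane shape.

    The indicator is a smoothed Heaviside of the signed height above the
    membrane curve with transition half-width ``halfwidth`` lattice units
    (monotone within a band of about 2*halfwidth nodes).
    """
    ny, nx = lattice_shape
    hx = membrane_height_profile(membrane, nx)
    if layer is None:
        layer = LayerMap(indicator=np.empty((ny, nx)), nu_pcl=nu_pcl,
                         nu_ml=nu_ml, halfwidth=halfwidth)
    K.layer_indicator_kernel(hx, layer.indicator, layer.halfwidth)
    return layer
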