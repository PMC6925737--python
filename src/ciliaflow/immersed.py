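"""Immersed-boundary coupling: regularized-delta spreading and interpolation.

Lagrangian points (cilium nodes, membrane nodes, particle surface points,
tracers) exchange force and velocity with the Eulerian lattice through a
tensor-product regularized delta kernel.  The domain is periodic in x; in y
the kernel is truncated at the walls (momentum pushed "into" a wall is
absorbed by it, and the fluid velocity outside the domain is taken as zero,
consistent with the no-slip wall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K

__all__ = ["DeltaKernel", "PESKIN4", "ROMA3", "HAT2", "spread_force",
           "interpolate_velocity"]


@dataclass(frozen=True)
class DeltaKernel:
    """Regularized delta function with finite support.

    ``support`` is the full width in lattice units (2 -> hat kernel,
    4 -> Peskin cosine-like 4-point kernel).  Both satisfy the discrete
    partition of unity sum_i phi(i - X) = 1 for any real X.
    """

    support: int = 4

    def __post_init__(self) -> None:
        if self.support not in (2, 3, 4):
            raise ValueError(
                "supported kernels: 2-point hat, 3-point Roma, 4-point Peskin")

    def phi(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        a = np.abs(r)
        if self.support == 2:
            m = a < 1.0
            out[m] = 1.0 - a[m]
            return out
        if self.support == 3:
            m = a <= 0.5
            out[m] = (1.0 + np.sqrt(1.0 - 3.0 * a[m] ** 2)) / 3.0
            m2 = (a > 0.5) & (a < 1.5)
            out[m2] = (5.0 - 3.0 * a[m2]
                       - np.sqrt(1.0 - 3.0 * (1.0 - a[m2]) ** 2)) / 6.0
            return out
        m1 = a <= 1.0
        out[m1] = 0.125 * (3 - 2 * a[m1] + np.sqrt(1 + 4 * a[m1] - 4 * a[m1] ** 2))
        m2 = (a > 1.0) & (a < 2.0)
        out[m2] = 0.125 * (5 - 2 * a[m2] - np.sqrt(-7 + 12 * a[m2] - 4 * a[m2] ** 2))
        return out


PESKIN4 = DeltaKernel(support=4)
ROMA3 = DeltaKernel(support=3)
HAT2 = DeltaKernel(support=2)


def _check_points(pts: np.ndarray, ny: int) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) arrays of (x, y)")
    if np.any(pts[:, 1] < -0.5) or np.any(pts[:, 1] > ny - 0.5):
        raise ValueError("Lagrangian point outside the domain in y")
    return pts


def spread_force(points, forces, lattice_shape, kernel: DeltaKernel = PESKIN4,
                 ds=1.0, out: np.ndarray | None = None,
                 validate: bool = True) -> np.ndarray:
    """Spread point forces F(s) onto the lattice: f(x) = sum_s F(s) D(x - X_s) ds.

    Parameters
    ----------
    points : (n, 2) array of (x, y) positions (lattice units).
    forces : (n, 2) array of force per unit boundary length.
    lattice_shape : (ny, nx).
    ds : scalar or (n,) quadrature weight of each point.
    out : optional (2, ny, nx) field to accumulate into.

    Returns the (2, ny, nx) force-density field.
    """
    ny, nx = lattice_shape
    pts = _check_points(points, ny) if validate else np.asarray(points, float)
    frc = np.atleast_2d(np.asarray(forces, dtype=float))
    ds_arr = np.broadcast_to(np.asarray(ds, dtype=float), (pts.shape[0],))
    if not ds_arr.flags.c_contiguous:
        ds_arr = np.ascontiguousarray(ds_arr)
    if out is None:
        out = np.zeros((2, ny, nx))
    K.spread_kernel(np.ascontiguousarray(pts), np.ascontiguousarray(frc),
                    ds_arr, out[0], out[1], kernel.support)
    return out


def interpolate_velocity(u_field, points, kernel: DeltaKernel = PESKIN4,
                         validate: bool = True) -> np.ndarray:
    """Interpolate the lattice velocity at Lagrangian points.

    U(s) = sum_x u(x) D(x - X_s) dx^2.  Returns an (n, 2) array.
    """
    ux, uy = u_field[0], u_field[1]
    pts = (_check_points(points, ux.shape[0]) if validate
           else np.asarray(points, float))
    out = np.empty_like(pts)
    K.interp_kernel(ux, uy, np.ascontiguousarray(pts), out, kernel.support)
    return out
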