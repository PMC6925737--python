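"""Deterministic generators of analytic test inputs.

Every fixture carries its own closed-form oracle values (computed here,
independently of the solver code paths it exercises), so the test suite
needs no external data.
"""

from __future__ import annotations

import numpy as np

from .fibers import Fiber

__all__ = ["make_analytic_field", "make_fiber_shape", "random_smooth_field",
           "converging_velocity_log"]


def make_analytic_field(kind: str, ny: int, nx: int, **params):
    """Closed-form velocity field on an (ny, nx) lattice.

    Kinds
    -----
    ``uniform``: constant ``c=(cx, cy)``; D = 0.
    ``shear``: ``u = (gdot * y, 0)``; D_xy = gdot/2.
    ``poiseuille``: ``u_x = 4 u_max y (Ly - y)/Ly^2`` with y = j + 1/2,
        Ly = ny.
    ``shear_wave``: ``u_x = A sin(2 pi y / ny)`` (periodic decaying mode).

    Returns ``(u, info)`` with ``u`` of shape (2, ny, nx) and ``info`` a dict
    of oracle quantities (e.g. the exact strain-rate components).
    """
    y = np.arange(ny, dtype=float)[:, None] * np.ones((1, nx))
    u = np.zeros((2, ny, nx))
    info: dict = {}
    if kind == "uniform":
        cx, cy = params.get("c", (0.1, 0.0))
        u[0] += cx
        u[1] += cy
        info["D"] = np.zeros((ny, nx, 2, 2))
    elif kind == "shear":
        gdot = params.get("gdot", 0.01)
        u[0] = gdot * y
        D = np.zeros((ny, nx, 2, 2))
        D[..., 0, 1] = D[..., 1, 0] = gdot / 2
        info["D"] = D
        info["gdot"] = gdot
    elif kind == "poiseuille":
        u_max = params.get("u_max", 0.1)
        Ly = float(ny)
        yy = y + 0.5
        u[0] = 4 * u_max * yy * (Ly - yy) / Ly ** 2
        info["u_max"] = u_max
        info["Ly"] = Ly
    elif kind == "shear_wave":
        A = params.get("A", 0.01)
        k = 2 * np.pi / ny
        u[0] = A * np.sin(k * y)
        info["A"] = A
        info["k"] = k
    else:
        raise ValueError(f"unknown analytic field kind: {kind!r}")
    return u, info


def make_fiber_shape(kind: str, n_nodes: int = 21, **params):
    """Analytic fiber shapes with known stretching/bending oracles.

    ``straight``: rest-length vertical fiber -> zero internal force.
    ``stretched``: straight fiber with uniform strain ``eps`` -> constant
        tension ``Ks * eps``; interior nodes force-free.
    ``sinusoid``: ``y(s) = a sin(k s)`` transverse wave on a long fiber ->
        interior bending force density ``-Kb a k^4 sin(k s)`` (restoring).

    Returns ``(fiber, info)``.
    """
    if n_nodes < 5:
        raise ValueError("need at least 5 nodes")
    ds = params.get("ds", 1.0)
    s = np.arange(n_nodes) * ds
    if kind == "straight":
        X = np.column_stack([np.zeros(n_nodes), s])
        info = {}
    elif kind == "stretched":
        eps = params.get("eps", 0.01)
        X = np.column_stack([np.zeros(n_nodes), s * (1 + eps)])
        info = {"tension": params.get("Ks", 2.0) * eps, "eps": eps}
    elif kind == "sinusoid":
        a = params.get("a", 0.05)
        k = params.get("k", 2 * np.pi / ((n_nodes - 1) * ds / 3))
        X = np.column_stack([a * np.sin(k * s), s])
        info = {"a": a, "k": k, "s": s,
                "bend_force_x": -params.get("Kb", 1.0) * a * k ** 4 * np.sin(k * s)}
    else:
        raise ValueError(f"unknown fiber shape kind: {kind!r}")
    fiber = Fiber(X=X, rest_ds=ds, Ks=params.get("Ks", 2.0),
                  Kb=params.get("Kb", 1.0))
    return fiber, info


def random_smooth_field(ny: int, nx: int, seed: int = 0, n_modes: int = 3,
                        amplitude: float = 0.01):
    """Smooth periodic velocity field from a fixed low-order Fourier basis.

    Returns ``(u, L_exact)`` where ``L_exact[a, b]`` holds the analytic
    velocity-gradient components du_a/dx_b, shape (2, 2, ny, nx).  Periodic
    in both directions, so centered differences apply everywhere except the
    y-walls (tests compare interior rows only).
    """
    rng = np.random.default_rng(seed)
    x = np.arange(nx)[None, :] * np.ones((ny, 1))
    y = np.arange(ny)[:, None] * np.ones((1, nx))
    u = np.zeros((2, ny, nx))
    L = np.zeros((2, 2, ny, nx))
    for _ in range(n_modes):
        kx = 2 * np.pi * rng.integers(1, 3) / nx
        ky = 2 * np.pi * rng.integers(1, 3) / ny
        for comp in range(2):
            a = amplitude * rng.uniform(0.3, 1.0)
            px, py = rng.uniform(0, 2 * np.pi, 2)
            u[comp] += a * np.sin(kx * x + px) * np.sin(ky * y + py)
            L[comp, 0] += a * kx * np.cos(kx * x + px) * np.sin(ky * y + py)
            L[comp, 1] += a * ky * np.sin(kx * x + px) * np.cos(ky * y + py)
    return u, L


def converging_velocity_log(n_periods: int = 30, v_inf: float = 40.0,
                            rate: float = 0.5, v0: float = 0.0) -> np.ndarray:
    """Synthetic per-period velocity log converging exponentially to v_inf."""
    k = np.arange(n_periods)
    return v_inf + (v0 - v_inf) * np.exp(-rate * k)
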