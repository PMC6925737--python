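"""Numba-compiled inner loops shared by the solver modules.

Everything here assumes unit lattice spacing and time step (dx = dt = 1,
cs^2 = 1/3) and arrays indexed ``[j, i]`` = ``[y, x]`` with periodic wrap in
x.  The public modules wrap these kernels with validated, documented APIs;
tests compare them against straightforward numpy implementations.
"""

import numpy as np
from numba import njit

# D2Q9 velocity set; must match lattice.E
_EX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
_EY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
_W = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36])
_OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64)


@njit(cache=True)
def collide_stream_kernel(g, gn, tmp, rho, ux, uy, fx, fy, tau, bot_code, top_code):
    """BGK collide + stream; bot/top codes: 0 periodic, 1 no-slip (halfway
    bounce-back), 2 slip (specular).

    Collision is evaluated per direction with branch-free inner loops (the
    compiler vectorizes them); streaming shifts whole rows with the periodic
    wrap handled by split index ranges.  ``tmp`` holds the post-collision
    state, ``gn`` the streamed result.
    """
    ny, nx = rho.shape
    inv_t = np.empty(nx)
    pref = np.empty(nx)
    # row-blocked loop order: the six macroscopic rows stay cache-resident
    # across the nine directions, and the relaxation divisions are hoisted
    for j in range(ny):
        rj = rho[j]
        uxj = ux[j]
        uyj = uy[j]
        fxj = fx[j]
        fyj = fy[j]
        tj = tau[j]
        for i in range(nx):
            inv_t[i] = 1.0 / tj[i]
            pref[i] = 1.0 - 0.5 * inv_t[i]
        for k in range(9):
            exk = float(_EX[k])
            eyk = float(_EY[k])
            wk = _W[k]
            gk = g[k, j]
            tk = tmp[k, j]
            for i in range(nx):
                vx = uxj[i]
                vy = uyj[i]
                eu = exk * vx + eyk * vy
                feq = wk * rj[i] * (1.0 + 3.0 * eu + 4.5 * eu * eu
                                    - 1.5 * (vx * vx + vy * vy))
                # Guo: w_k [3 (e-u) + 9 (e.u) e] . f
                G = (pref[i] * wk
                     * ((3.0 * (exk - vx) + 9.0 * eu * exk) * fxj[i]
                        + (3.0 * (eyk - vy) + 9.0 * eu * eyk) * fyj[i]))
                tk[i] = gk[i] - (gk[i] - feq) * inv_t[i] + G
    # streaming with periodic wrap in both directions
    for k in range(9):
        ei = _EX[k]
        for j in range(ny):
            jd = (j + _EY[k]) % ny
            src = tmp[k, j]
            dst = gn[k, jd]
            if ei == 0:
                for i in range(nx):
                    dst[i] = src[i]
            elif ei == 1:
                for i in range(nx - 1):
                    dst[i + 1] = src[i]
                dst[0] = src[nx - 1]
            else:
                for i in range(1, nx):
                    dst[i - 1] = src[i]
                dst[nx - 1] = src[0]
    # bottom edge (j = 0): unknowns are the upward populations 2, 5, 6
    if bot_code == 1:  # halfway bounce-back
        for i in range(nx):
            gn[2, 0, i] = tmp[4, 0, i]
            gn[5, 0, i] = tmp[7, 0, i]
            gn[6, 0, i] = tmp[8, 0, i]
    elif bot_code == 2:  # specular (free-slip)
        for i in range(nx):
            gn[2, 0, i] = tmp[4, 0, i]
            gn[5, 0, i] = tmp[8, 0, (i - 1) % nx]
            gn[6, 0, i] = tmp[7, 0, (i + 1) % nx]
    # top edge (j = ny-1): unknowns are the downward populations 4, 7, 8
    if top_code == 1:
        for i in range(nx):
            gn[4, ny - 1, i] = tmp[2, ny - 1, i]
            gn[7, ny - 1, i] = tmp[5, ny - 1, i]
            gn[8, ny - 1, i] = tmp[6, ny - 1, i]
    elif top_code == 2:
        for i in range(nx):
            gn[4, ny - 1, i] = tmp[2, ny - 1, i]
            gn[7, ny - 1, i] = tmp[6, ny - 1, (i + 1) % nx]
            gn[8, ny - 1, i] = tmp[5, ny - 1, (i - 1) % nx]
    return gn


@njit(cache=True)
def macroscopic_kernel(g, rho, ux, uy, fx, fy):
    """Moments with Guo half-force shift; returns 0 if healthy, 1 if any
    node has non-positive or non-finite density (NaN-safe comparison)."""
    ny, nx = rho.shape
    bad = 0
    for j in range(ny):
        for i in range(nx):
            r = 0.0
            mx = 0.0
            my = 0.0
            for k in range(9):
                gk = g[k, j, i]
                r += gk
                mx += gk * _EX[k]
                my += gk * _EY[k]
            if not (r > 0.0):
                bad = 1
                r = 1.0
            rho[j, i] = r
            ux[j, i] = (mx + 0.5 * fx[j, i]) / r
            uy[j, i] = (my + 0.5 * fy[j, i]) / r
    return bad


@njit(cache=True, inline="always")
def _ddx(a, j, i, nx):
    """Centered x-derivative with periodic wrap."""
    return 0.5 * (a[j, (i + 1) % nx] - a[j, (i - 1) % nx])


@njit(cache=True, inline="always")
def _ddy(a, j, i, ny):
    """Centered y-derivative, second-order one-sided at walls."""
    if j == 0:
        return 0.5 * (-3.0 * a[0, i] + 4.0 * a[1, i] - a[2, i])
    if j == ny - 1:
        return 0.5 * (3.0 * a[ny - 1, i] - 4.0 * a[ny - 2, i] + a[ny - 3, i])
    return 0.5 * (a[j + 1, i] - a[j - 1, i])


@njit(cache=True)
def velocity_gradient_kernel(ux, uy, lxx, lxy, lyx, lyy):
    """L_ab = d u_a / d x_b by centered differences (periodic x, one-sided y)."""
    ny, nx = ux.shape
    for j in range(ny):
        for i in range(nx):
            lxx[j, i] = _ddx(ux, j, i, nx)
            lxy[j, i] = _ddy(ux, j, i, ny)
            lyx[j, i] = _ddx(uy, j, i, nx)
            lyy[j, i] = _ddy(uy, j, i, ny)


@njit(cache=True)
def stress_step_kernel(sxx, sxy, syy, nxx, nxy, nyy, ux, uy, ind,
                       eta_e_ml, lam, dt, kappa):
    """One explicit step of the upper-convected Maxwell stress transport.

    d sigma/dt = -u.grad(sigma) + L.sigma + sigma.L^T + (2 eta_E D - sigma)/lam
    + kappa Lap(sigma), with first-order upwind advection.  ``eta_E`` is
    ``eta_e_ml * ind`` so the elastic source lives only in the mucus layer;
    outside it the stress is advected and relaxed to zero.  ``kappa`` is a
    small stress diffusivity (the standard regularization of the UCM law:
    it bounds the growth of kernel-scale stress pockets whose local
    Weissenberg number exceeds the coil-stretch threshold).  Writes the
    updated components into nxx/nxy/nyy.
    """
    ny, nx = sxx.shape
    for j in range(ny):
        for i in range(nx):
            vx = ux[j, i]
            vy = uy[j, i]
            # upwind advection
            if vx > 0.0:
                axx = vx * (sxx[j, i] - sxx[j, (i - 1) % nx])
                axy = vx * (sxy[j, i] - sxy[j, (i - 1) % nx])
                ayy = vx * (syy[j, i] - syy[j, (i - 1) % nx])
            else:
                axx = vx * (sxx[j, (i + 1) % nx] - sxx[j, i])
                axy = vx * (sxy[j, (i + 1) % nx] - sxy[j, i])
                ayy = vx * (syy[j, (i + 1) % nx] - syy[j, i])
            if vy > 0.0:
                jm = j - 1 if j > 0 else 0
                axx += vy * (sxx[j, i] - sxx[jm, i])
                axy += vy * (sxy[j, i] - sxy[jm, i])
                ayy += vy * (syy[j, i] - syy[jm, i])
            else:
                jp = j + 1 if j < ny - 1 else ny - 1
                axx += vy * (sxx[jp, i] - sxx[j, i])
                axy += vy * (sxy[jp, i] - sxy[j, i])
                ayy += vy * (syy[jp, i] - syy[j, i])
            # velocity gradient
            lxx = _ddx(ux, j, i, nx)
            lxy = _ddy(ux, j, i, ny)
            lyx = _ddx(uy, j, i, nx)
            lyy = _ddy(uy, j, i, ny)
            xx = sxx[j, i]
            xy = sxy[j, i]
            yy = syy[j, i]
            # L.sigma + sigma.L^T
            uxx = 2.0 * (lxx * xx + lxy * xy)
            uxy = lyx * xx + lyy * xy + lxx * xy + lxy * yy
            uyy = 2.0 * (lyx * xy + lyy * yy)
            eta_e = eta_e_ml * ind[j, i]
            dxx = 2.0 * eta_e * lxx
            dxy = eta_e * (lxy + lyx)
            dyy = 2.0 * eta_e * lyy
            if kappa > 0.0:
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                im = (i - 1) % nx
                ip = (i + 1) % nx
                lap_xx = (sxx[jm, i] + sxx[jp, i] + sxx[j, im] + sxx[j, ip]
                          - 4.0 * xx)
                lap_xy = (sxy[jm, i] + sxy[jp, i] + sxy[j, im] + sxy[j, ip]
                          - 4.0 * xy)
                lap_yy = (syy[jm, i] + syy[jp, i] + syy[j, im] + syy[j, ip]
                          - 4.0 * yy)
            else:
                lap_xx = 0.0
                lap_xy = 0.0
                lap_yy = 0.0
            # relaxation and source handled implicitly: stable for any lam,
            # with the correct quasi-Newtonian limit sigma -> 2 eta_E D
            denom = 1.0 + dt / lam
            nxx[j, i] = (xx + dt * (-axx + uxx + dxx / lam
                                    + kappa * lap_xx)) / denom
            nxy[j, i] = (xy + dt * (-axy + uxy + dxy / lam
                                    + kappa * lap_xy)) / denom
            nyy[j, i] = (yy + dt * (-ayy + uyy + dyy / lam
                                    + kappa * lap_yy)) / denom


@njit(cache=True)
def stress_divergence_kernel(sxx, sxy, syy, ind, fx, fy):
    """f = div(ind * sigma) by centered differences; adds into fx, fy."""
    ny, nx = sxx.shape
    for j in range(ny):
        for i in range(nx):
            # products with the indicator, evaluated at the stencil points
            dsxx = _ddx2(sxx, ind, j, i, nx)
            dsxy_y = _ddy2(sxy, ind, j, i, ny)
            dsxy_x = _ddx2(sxy, ind, j, i, nx)
            dsyy = _ddy2(syy, ind, j, i, ny)
            fx[j, i] += dsxx + dsxy_y
            fy[j, i] += dsxy_x + dsyy


@njit(cache=True, inline="always")
def _ddx2(a, m, j, i, nx):
    ip = (i + 1) % nx
    im = (i - 1) % nx
    return 0.5 * (a[j, ip] * m[j, ip] - a[j, im] * m[j, im])


@njit(cache=True, inline="always")
def _ddy2(a, m, j, i, ny):
    if j == 0:
        return 0.5 * (-3.0 * a[0, i] * m[0, i] + 4.0 * a[1, i] * m[1, i]
                      - a[2, i] * m[2, i])
    if j == ny - 1:
        return 0.5 * (3.0 * a[ny - 1, i] * m[ny - 1, i]
                      - 4.0 * a[ny - 2, i] * m[ny - 2, i]
                      + a[ny - 3, i] * m[ny - 3, i])
    return 0.5 * (a[j + 1, i] * m[j + 1, i] - a[j - 1, i] * m[j - 1, i])


# ---------------------------------------------------------------------------
# immersed-boundary kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def peskin4(r):
    """Peskin 4-point regularized delta (1D factor)."""
    a = abs(r)
    if a >= 2.0:
        return 0.0
    if a <= 1.0:
        return 0.125 * (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a))
    return 0.125 * (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a))


@njit(cache=True, inline="always")
def hat2(r):
    """2-point hat kernel (1D factor)."""
    a = abs(r)
    return 1.0 - a if a < 1.0 else 0.0


@njit(cache=True, inline="always")
def roma3(r):
    """Roma-Peskin 3-point kernel (1D factor), support |r| < 1.5."""
    a = abs(r)
    if a >= 1.5:
        return 0.0
    if a <= 0.5:
        return (1.0 + np.sqrt(1.0 - 3.0 * a * a)) / 3.0
    return (5.0 - 3.0 * a - np.sqrt(1.0 - 3.0 * (1.0 - a) ** 2)) / 6.0


@njit(cache=True)
def spread_kernel(pts, frc, ds, fx, fy, support):
    """Spread Lagrangian forces onto the lattice (periodic x, truncated y).

    ``pts``/``frc`` are (n, 2); ``ds`` is the per-point quadrature weight
    (segment length).  ``support`` selects the kernel: 2 -> hat, else
    4-point Peskin.
    """
    ny, nx = fx.shape
    n = pts.shape[0]
    half = 1 if support == 2 else 2
    for p in range(n):
        X = pts[p, 0]
        Y = pts[p, 1]
        wX = frc[p, 0] * ds[p]
        wY = frc[p, 1] * ds[p]
        i0 = int(np.floor(X)) - half + 1
        j0 = int(np.floor(Y)) - half + 1
        for jj in range(j0, j0 + 2 * half):
            if jj < 0 or jj >= ny:
                continue
            if support == 2:
                py = hat2(jj - Y)
            elif support == 3:
                py = roma3(jj - Y)
            else:
                py = peskin4(jj - Y)
            if py == 0.0:
                continue
            for ii in range(i0, i0 + 2 * half):
                if support == 2:
                    px = hat2(ii - X)
                elif support == 3:
                    px = roma3(ii - X)
                else:
                    px = peskin4(ii - X)
                if px == 0.0:
                    continue
                w = px * py
                iw = ii % nx
                fx[jj, iw] += wX * w
                fy[jj, iw] += wY * w


@njit(cache=True)
def interp_kernel(ux, uy, pts, out, support):
    """Interpolate lattice velocity at Lagrangian points (periodic x)."""
    ny, nx = ux.shape
    n = pts.shape[0]
    half = 1 if support == 2 else 2
    for p in range(n):
        X = pts[p, 0]
        Y = pts[p, 1]
        sx = 0.0
        sy = 0.0
        i0 = int(np.floor(X)) - half + 1
        j0 = int(np.floor(Y)) - half + 1
        for jj in range(j0, j0 + 2 * half):
            if jj < 0 or jj >= ny:
                continue
            if support == 2:
                py = hat2(jj - Y)
            elif support == 3:
                py = roma3(jj - Y)
            else:
                py = peskin4(jj - Y)
            if py == 0.0:
                continue
            for ii in range(i0, i0 + 2 * half):
                if support == 2:
                    px = hat2(ii - X)
                elif support == 3:
                    px = roma3(ii - X)
                else:
                    px = peskin4(ii - X)
                if px == 0.0:
                    continue
                w = px * py
                iw = ii % nx
                sx += ux[jj, iw] * w
                sy += uy[jj, iw] * w
        out[p, 0] = sx
        out[p, 1] = sy


# ---------------------------------------------------------------------------
# fiber force kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def open_fiber_forces(X, ks, kb, ds, F):
    """Stretching + bending force (per unit length) of one open fiber.

    X: (n, 2) node positions, F: (n, 2) output (overwritten).
    Stretching: nodal difference of segment tensions T_j = ks (|dX|/ds - 1).
    Bending: F_b = -kb D2^T D2 X / ds^4 (natural free-end conditions,
    curvature evaluated at interior nodes only), normalized per unit length.
    """
    n = X.shape[0]
    for a in range(n):
        F[a, 0] = 0.0
        F[a, 1] = 0.0
    # stretching
    for jseg in range(n - 1):
        dx = X[jseg + 1, 0] - X[jseg, 0]
        dy = X[jseg + 1, 1] - X[jseg, 1]
        ell = np.sqrt(dx * dx + dy * dy)
        T = ks * (ell / ds - 1.0)
        tx = dx / ell
        ty = dy / ell
        # tension pulls the two end nodes together/apart
        F[jseg, 0] += T * tx / ds
        F[jseg, 1] += T * ty / ds
        F[jseg + 1, 0] -= T * tx / ds
        F[jseg + 1, 1] -= T * ty / ds
    # bending: curvature vector at interior nodes
    if kb != 0.0 and n >= 5:
        inv4 = 1.0 / ds ** 4
        for c in range(1, n - 1):
            kx = X[c - 1, 0] - 2.0 * X[c, 0] + X[c + 1, 0]
            ky = X[c - 1, 1] - 2.0 * X[c, 1] + X[c + 1, 1]
            # distribute -kb * D2^T (D2 X) onto the stencil nodes
            F[c - 1, 0] -= kb * kx * inv4
            F[c - 1, 1] -= kb * ky * inv4
            F[c, 0] += 2.0 * kb * kx * inv4
            F[c, 1] += 2.0 * kb * ky * inv4
            F[c + 1, 0] -= kb * kx * inv4
            F[c + 1, 1] -= kb * ky * inv4


@njit(cache=True)
def closed_fiber_forces(X, ks, kb, ds, Lx, F):
    """Stretching + bending force of a fiber closed periodically in x.

    Node x-coordinates are unbounded (not wrapped); the closure segment from
    the last node back to the first is displaced by the channel length Lx.
    """
    n = X.shape[0]
    for a in range(n):
        F[a, 0] = 0.0
        F[a, 1] = 0.0
    for jseg in range(n):
        jn = jseg + 1
        shift = 0.0
        if jn == n:
            jn = 0
            shift = Lx
        dx = X[jn, 0] + shift - X[jseg, 0]
        dy = X[jn, 1] - X[jseg, 1]
        ell = np.sqrt(dx * dx + dy * dy)
        T = ks * (ell / ds - 1.0)
        tx = dx / ell
        ty = dy / ell
        F[jseg, 0] += T * tx / ds
        F[jseg, 1] += T * ty / ds
        F[jn, 0] -= T * tx / ds
        F[jn, 1] -= T * ty / ds
    if kb != 0.0:
        inv4 = 1.0 / ds ** 4
        for c in range(n):
            cm = c - 1
            cp = c + 1
            sm = 0.0
            sp = 0.0
            if cm < 0:
                cm = n - 1
                sm = -Lx
            if cp >= n:
                cp = 0
                sp = Lx
            kx = X[cm, 0] + sm - 2.0 * X[c, 0] + X[cp, 0] + sp
            ky = X[cm, 1] - 2.0 * X[c, 1] + X[cp, 1]
            F[cm, 0] -= kb * kx * inv4
            F[cm, 1] -= kb * ky * inv4
            F[c, 0] += 2.0 * kb * kx * inv4
            F[c, 1] += 2.0 * kb * ky * inv4
            F[cp, 0] -= kb * kx * inv4
            F[cp, 1] -= kb * ky * inv4


@njit(cache=True)
def cilia_explicit_forces_kernel(Xb, Vb, Ub, ks, eta_d, ds, Fb):
    """Explicit part of the cilium force: stretching + tether damper.

    The linear stiff parts (bending, penalty spring) are handled implicitly
    by the caller; this kernel returns only the nonlinear tension and the
    spring-damper velocity term ``eta_d (V_Y - U)``.
    """
    n_cil, n_nodes = Xb.shape[0], Xb.shape[1]
    for c in range(n_cil):
        open_fiber_forces(Xb[c], ks, 0.0, ds, Fb[c])
        for j in range(n_nodes):
            Fb[c, j, 0] += eta_d * (Vb[c, j, 0] - Ub[c, j, 0])
            Fb[c, j, 1] += eta_d * (Vb[c, j, 1] - Ub[c, j, 1])


@njit(cache=True)
def layer_indicator_kernel(hx, ind, halfwidth):
    """Smoothed Heaviside of the signed height above the membrane curve.

    hx: membrane height per lattice column (nx,), in node-index coordinates
    (node j sits at y = j; the physical walls are half a cell outside).
    """
    ny, nx = ind.shape
    for i in range(nx):
        h = hx[i]
        for j in range(ny):
            y = float(j)
            r = (y - h) / halfwidth
            if r <= -1.0:
                ind[j, i] = 0.0
            elif r >= 1.0:
                ind[j, i] = 1.0
            else:
                ind[j, i] = 0.5 * (1.0 + r + np.sin(np.pi * r) / np.pi)


@njit(cache=True)
def particle_repulsion_kernel(cen, rad, fib, nx, ny, C, cut, Fp, Ffib):
    """Short-range quadratic repulsion for all particles at once.

    cen/rad: particle centers (n,2) and radii (n,); fib: fiber contact
    points (m,2) (cilium nodes); periodic minimum-image in x.  Adds
    particle forces into Fp (n,2) and opposite reactions into Ffib (m,2).
    """
    n = cen.shape[0]
    m = fib.shape[0]
    for a in range(n):
        # walls
        gap = cen[a, 1] - rad[a] + 0.5
        if gap < cut:
            g = gap if gap > 0.0 else 0.0
            Fp[a, 1] += C * ((cut - g) / cut) ** 2
        gap = (ny - 0.5) - cen[a, 1] - rad[a]
        if gap < cut:
            g = gap if gap > 0.0 else 0.0
            Fp[a, 1] -= C * ((cut - g) / cut) ** 2
        # other particles
        for b in range(a + 1, n):
            dx = cen[a, 0] - cen[b, 0]
            dx -= nx * np.rint(dx / nx)
            dy = cen[a, 1] - cen[b, 1]
            reach = rad[a] + rad[b] + cut
            if dx * dx + dy * dy >= reach * reach:
                continue
            dist = np.sqrt(dx * dx + dy * dy)
            if dist < 1e-12:
                continue
            gap = dist - rad[a] - rad[b]
            if gap < cut:
                g = gap if gap > 0.0 else 0.0
                f = C * ((cut - g) / cut) ** 2 / dist
                Fp[a, 0] += f * dx
                Fp[a, 1] += f * dy
                Fp[b, 0] -= f * dx
                Fp[b, 1] -= f * dy
        # fiber nodes
        reach = rad[a] + cut
        for q in range(m):
            dy = cen[a, 1] - fib[q, 1]
            if dy > reach or dy < -reach:
                continue
            dx = cen[a, 0] - fib[q, 0]
            dx -= nx * np.rint(dx / nx)
            if dx > reach or dx < -reach:
                continue
            dist = np.sqrt(dx * dx + dy * dy)
            if dist < 1e-12:
                continue
            gap = dist - rad[a]
            if gap < cut:
                g = gap if gap > 0.0 else 0.0
                f = C * ((cut - g) / cut) ** 2 / dist
                Fp[a, 0] += f * dx
                Fp[a, 1] += f * dy
                Ffib[q, 0] -= f * dx
                Ffib[q, 1] -= f * dy
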