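"""Numba stencil kernels for the time-domain acoustic solvers.

All kernels operate on C-contiguous 3D arrays and are written for
single-threaded execution.  The spatial operator is the flux form
ρ∇·(1/ρ∇p): face fluxes F = (1/ρ)_face·∂p/∂ξ are assembled first (with the
CPML-stretched derivative), then the divergence (also stretched) closes the
update.  Face-averaged 1/ρ is the arithmetic mean of the neighboring
voxels' 1/ρ, which preserves continuity of normal velocity across material
interfaces.  Singleton axes are skipped, so thin-slab (quasi-2D) and line
(1D) domains run with the same kernels.
"""

import numba
import numpy as np

_OPTS = dict(fastmath=True, cache=True, nogil=True)


@numba.njit(**_OPTS)
def flux_x(p, invrho, Fx, inv_dxf, b_f, a_f, psi):
    nx, ny, nz = p.shape
    for i in range(nx - 1):
        inv = inv_dxf[i]
        bi = b_f[i]
        ai = a_f[i]
        in_pml = ai != 0.0
        for j in range(ny):
            for k in range(nz):
                g = (p[i + 1, j, k] - p[i, j, k]) * inv
                if in_pml:
                    ps = bi * psi[i, j, k] + ai * g
                    psi[i, j, k] = ps
                    g = g + ps
                Fx[i, j, k] = 0.5 * (invrho[i, j, k] + invrho[i + 1, j, k]) * g


@numba.njit(**_OPTS)
def flux_y(p, invrho, Fy, inv_dyf, b_f, a_f, psi):
    nx, ny, nz = p.shape
    for i in range(nx):
        for j in range(ny - 1):
            inv = inv_dyf[j]
            bj = b_f[j]
            aj = a_f[j]
            in_pml = aj != 0.0
            for k in range(nz):
                g = (p[i, j + 1, k] - p[i, j, k]) * inv
                if in_pml:
                    ps = bj * psi[i, j, k] + aj * g
                    psi[i, j, k] = ps
                    g = g + ps
                Fy[i, j, k] = 0.5 * (invrho[i, j, k] + invrho[i, j + 1, k]) * g


@numba.njit(**_OPTS)
def flux_z(p, invrho, Fz, inv_dzf, b_f, a_f, psi):
    nx, ny, nz = p.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz - 1):
                g = (p[i, j, k + 1] - p[i, j, k]) * inv_dzf[k]
                ak = a_f[k]
                if ak != 0.0:
                    ps = b_f[k] * psi[i, j, k] + ak * g
                    psi[i, j, k] = ps
                    g = g + ps
                Fz[i, j, k] = 0.5 * (invrho[i, j, k] + invrho[i, j, k + 1]) * g


@numba.njit(**_OPTS)
def update_lapwe(
    p, p_prev, Fx, Fy, Fz,
    inv_dxc, inv_dyc, inv_dzc,
    bx, ax, by, ay, bz, az,
    phix, phiy, phiz,
    A, ad,
    do_x, do_y, do_z,
):
    """One leapfrog step of the damped linear wave equation.

    p⁺·(1 + ãdt/2) = 2p − (1 − ãdt/2)p⁻ + dt²c²ρ·∇·(1/ρ∇p).
    ``A`` holds dt²c²ρ, ``ad`` holds ãdt/2.  The new level is written into
    ``p_prev`` in place (caller swaps buffers).  ``do_*`` disable the
    divergence along singleton axes.
    """
    nx, ny, nz = p.shape
    i0, i1 = (1, nx - 1) if do_x else (0, nx)
    j0, j1 = (1, ny - 1) if do_y else (0, ny)
    k0, k1 = (1, nz - 1) if do_z else (0, nz)
    for i in range(i0, i1):
        for j in range(j0, j1):
            for k in range(k0, k1):
                L = 0.0
                if do_x:
                    d = (Fx[i, j, k] - Fx[i - 1, j, k]) * inv_dxc[i]
                    if ax[i] != 0.0:
                        ph = bx[i] * phix[i, j, k] + ax[i] * d
                        phix[i, j, k] = ph
                        d = d + ph
                    L += d
                if do_y:
                    d = (Fy[i, j, k] - Fy[i, j - 1, k]) * inv_dyc[j]
                    if ay[j] != 0.0:
                        ph = by[j] * phiy[i, j, k] + ay[j] * d
                        phiy[i, j, k] = ph
                        d = d + ph
                    L += d
                if do_z:
                    d = (Fz[i, j, k] - Fz[i, j, k - 1]) * inv_dzc[k]
                    if az[k] != 0.0:
                        ph = bz[k] * phiz[i, j, k] + az[k] * d
                        phiz[i, j, k] = ph
                        d = d + ph
                    L += d
                adv = ad[i, j, k]
                p_prev[i, j, k] = (
                    2.0 * p[i, j, k]
                    - (1.0 - adv) * p_prev[i, j, k]
                    + A[i, j, k] * L
                ) / (1.0 + adv)


@numba.njit(**_OPTS)
def update_wle(
    p, pm1, pm2, pm3, p_new,
    Fx, Fy, Fz,
    inv_dxc, inv_dyc, inv_dzc,
    bx, ax, by, ay, bz, az,
    phix, phiy, phiz,
    A, ad, gam, betafac,
    do_x, do_y, do_z,
):
    """One step of the Westervelt–Lighthill equation.

    Thermoviscous term (δ/c⁴)∂³p/∂t³ is discretized with a backward
    difference that is implicit-but-linear in p⁺; the nonlinear term
    (β/2ρc⁴)∂²p²/∂t² uses a second-order backward difference over the four
    stored levels.  ``gam`` = δ/(c²dt), ``betafac`` = β/(ρc²).
    """
    nx, ny, nz = p.shape
    i0, i1 = (1, nx - 1) if do_x else (0, nx)
    j0, j1 = (1, ny - 1) if do_y else (0, ny)
    k0, k1 = (1, nz - 1) if do_z else (0, nz)
    for i in range(i0, i1):
        for j in range(j0, j1):
            for k in range(k0, k1):
                L = 0.0
                if do_x:
                    d = (Fx[i, j, k] - Fx[i - 1, j, k]) * inv_dxc[i]
                    if ax[i] != 0.0:
                        ph = bx[i] * phix[i, j, k] + ax[i] * d
                        phix[i, j, k] = ph
                        d = d + ph
                    L += d
                if do_y:
                    d = (Fy[i, j, k] - Fy[i, j - 1, k]) * inv_dyc[j]
                    if ay[j] != 0.0:
                        ph = by[j] * phiy[i, j, k] + ay[j] * d
                        phiy[i, j, k] = ph
                        d = d + ph
                    L += d
                if do_z:
                    d = (Fz[i, j, k] - Fz[i, j, k - 1]) * inv_dzc[k]
                    if az[k] != 0.0:
                        ph = bz[k] * phiz[i, j, k] + az[k] * d
                        phiz[i, j, k] = ph
                        d = d + ph
                    L += d
                pc = p[i, j, k]
                p1 = pm1[i, j, k]
                p2 = pm2[i, j, k]
                p3 = pm3[i, j, k]
                g = gam[i, j, k]
                adv = ad[i, j, k]
                nl = betafac[i, j, k] * (
                    2.0 * pc * pc - 5.0 * p1 * p1 + 4.0 * p2 * p2 - p3 * p3
                )
                p_new[i, j, k] = (
                    2.0 * pc
                    - (1.0 - adv) * p1
                    + A[i, j, k] * L
                    + g * (-3.0 * pc + 3.0 * p1 - p2)
                    + nl
                ) / (1.0 - g + adv)


@numba.njit(**_OPTS)
def accumulate_phasor(p, acc_c, acc_s, wc, ws):
    """acc_c += p·cos(ωt), acc_s += p·sin(ωt) (single pass, in place)."""
    n = p.size
    pf = p.ravel()
    cf = acc_c.ravel()
    sf = acc_s.ravel()
    for idx in range(n):
        v = pf[idx]
        cf[idx] += v * wc
        sf[idx] += v * ws


# ---------------------------------------------------------------------------
# Specializations for homogeneous media (uniform ρ, c, ã; no air mask).
# The face flux reduces to the plain stretched gradient and all update
# coefficients collapse to scalars, which removes several full-array reads
# per step.  Used automatically by the solver when the volume is uniform.
# ---------------------------------------------------------------------------


@numba.njit(**_OPTS)
def flux_x_hom(p, Fx, inv_dxf, b_f, a_f, psi):
    nx, ny, nz = p.shape
    for i in range(nx - 1):
        inv = inv_dxf[i]
        bi = b_f[i]
        ai = a_f[i]
        in_pml = ai != 0.0
        for j in range(ny):
            for k in range(nz):
                g = (p[i + 1, j, k] - p[i, j, k]) * inv
                if in_pml:
                    ps = bi * psi[i, j, k] + ai * g
                    psi[i, j, k] = ps
                    g = g + ps
                Fx[i, j, k] = g


@numba.njit(**_OPTS)
def flux_y_hom(p, Fy, inv_dyf, b_f, a_f, psi):
    nx, ny, nz = p.shape
    for i in range(nx):
        for j in range(ny - 1):
            inv = inv_dyf[j]
            bj = b_f[j]
            aj = a_f[j]
            in_pml = aj != 0.0
            for k in range(nz):
                g = (p[i, j + 1, k] - p[i, j, k]) * inv
                if in_pml:
                    ps = bj * psi[i, j, k] + aj * g
                    psi[i, j, k] = ps
                    g = g + ps
                Fy[i, j, k] = g


@numba.njit(**_OPTS)
def flux_z_hom(p, Fz, inv_dzf, b_f, a_f, psi):
    nx, ny, nz = p.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz - 1):
                g = (p[i, j, k + 1] - p[i, j, k]) * inv_dzf[k]
                ak = a_f[k]
                if ak != 0.0:
                    ps = b_f[k] * psi[i, j, k] + ak * g
                    psi[i, j, k] = ps
                    g = g + ps
                Fz[i, j, k] = g


@numba.njit(**_OPTS)
def update_lapwe_hom(
    p, p_prev, Fx, Fy, Fz,
    inv_dxc, inv_dyc, inv_dzc,
    bx, ax, by, ay, bz, az,
    phix, phiy, phiz,
    r2, cprev, Ar,
    do_x, do_y, do_z,
):
    """Uniform-medium LAPWE step with scalar coefficients.

    r2 = 2/(1 + ãdt/2), cprev = (1 − ãdt/2)/(1 + ãdt/2),
    Ar = dt²c²/(1 + ãdt/2); fluxes carry no 1/ρ factor.
    """
    nx, ny, nz = p.shape
    i0, i1 = (1, nx - 1) if do_x else (0, nx)
    j0, j1 = (1, ny - 1) if do_y else (0, ny)
    k0, k1 = (1, nz - 1) if do_z else (0, nz)
    for i in range(i0, i1):
        x_pml = do_x and ax[i] != 0.0
        for j in range(j0, j1):
            y_pml = do_y and ay[j] != 0.0
            for k in range(k0, k1):
                L = 0.0
                if do_x:
                    d = (Fx[i, j, k] - Fx[i - 1, j, k]) * inv_dxc[i]
                    if x_pml:
                        ph = bx[i] * phix[i, j, k] + ax[i] * d
                        phix[i, j, k] = ph
                        d = d + ph
                    L += d
                if do_y:
                    d = (Fy[i, j, k] - Fy[i, j - 1, k]) * inv_dyc[j]
                    if y_pml:
                        ph = by[j] * phiy[i, j, k] + ay[j] * d
                        phiy[i, j, k] = ph
                        d = d + ph
                    L += d
                if do_z:
                    d = (Fz[i, j, k] - Fz[i, j, k - 1]) * inv_dzc[k]
                    if az[k] != 0.0:
                        ph = bz[k] * phiz[i, j, k] + az[k] * d
                        phiz[i, j, k] = ph
                        d = d + ph
                    L += d
                p_prev[i, j, k] = (
                    r2 * p[i, j, k] - cprev * p_prev[i, j, k] + Ar * L
                )
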