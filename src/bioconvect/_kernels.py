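"""Compiled inner loops: Thomas elimination and the two ADI half-sweeps.

Kept free of any package types so the functions stay cacheable and easy
to reason about: plain float64 arrays in, arrays out.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def thomas(a, b, c, d):
    """Solve a tridiagonal system in O(m); no pivoting.

    ``a`` is the sub-diagonal (a[0] unused), ``c`` the super-diagonal
    (c[-1] unused).  Callers guarantee diagonal dominance.
    """
    m = b.size
    cp = np.empty(m)
    dp = np.empty(m)
    beta = b[0]
    cp[0] = c[0] / beta
    dp[0] = d[0] / beta
    for k in range(1, m):
        beta = b[k] - a[k] * cp[k - 1]
        cp[k] = c[k] / beta
        dp[k] = (d[k] - a[k] * dp[k - 1]) / beta
    x = np.empty(m)
    x[m - 1] = dp[m - 1]
    for k in range(m - 2, -1, -1):
        x[k] = dp[k] - cp[k] * x[k + 1]
    return x


@njit(cache=True)
def coupled_step_fields(psi, n, theta, phi, dx1, dx2,
                        Sc, Ra, RaT, Ran, Le, r_rho, dBm, dTm):
    """One fused pass over the grid: velocity from psi (centred inside,
    second-order one-sided on the boundary rows) and the three explicit
    source fields (buoyancy for omega, Brownian/thermophoretic coupling
    for theta, thermophoretic lap(theta) for phi; interior nodes only).
    """
    n1, n2 = psi.shape
    u = np.empty((n1, n2))
    v = np.empty((n1, n2))
    S_om = np.zeros((n1, n2))
    S_th = np.zeros((n1, n2))
    S_ph = np.zeros((n1, n2))
    for i in range(n1):
        for j in range(n2):
            if 0 < j < n2 - 1:
                u[i, j] = (psi[i, j + 1] - psi[i, j - 1]) / (2.0 * dx2)
            elif j == 0:
                u[i, 0] = (-3.0 * psi[i, 0] + 4.0 * psi[i, 1] - psi[i, 2]) / (
                    2.0 * dx2
                )
            else:
                u[i, j] = (3.0 * psi[i, j] - 4.0 * psi[i, j - 1] + psi[i, j - 2]) / (
                    2.0 * dx2
                )
            if 0 < i < n1 - 1:
                v[i, j] = -(psi[i + 1, j] - psi[i - 1, j]) / (2.0 * dx1)
            elif i == 0:
                v[0, j] = -(-3.0 * psi[0, j] + 4.0 * psi[1, j] - psi[2, j]) / (
                    2.0 * dx1
                )
            else:
                v[i, j] = -(3.0 * psi[i, j] - 4.0 * psi[i - 1, j] + psi[i - 2, j]) / (
                    2.0 * dx1
                )
    for i in range(1, n1 - 1):
        for j in range(1, n2 - 1):
            dn1 = (n[i + 1, j] - n[i - 1, j]) / (2.0 * dx1)
            dth1 = (theta[i + 1, j] - theta[i - 1, j]) / (2.0 * dx1)
            dth2 = (theta[i, j + 1] - theta[i, j - 1]) / (2.0 * dx2)
            dph1 = (phi[i + 1, j] - phi[i - 1, j]) / (2.0 * dx1)
            dph2 = (phi[i, j + 1] - phi[i, j - 1]) / (2.0 * dx2)
            lap_th = (theta[i + 1, j] - 2.0 * theta[i, j] + theta[i - 1, j]) / (
                dx1 * dx1
            ) + (theta[i, j + 1] - 2.0 * theta[i, j] + theta[i, j - 1]) / (dx2 * dx2)
            S_om[i, j] = (
                -Sc * Ra * dn1 + Le * Sc * RaT * dth1 - Le * Sc * Ran * dph1
            )
            S_th[i, j] = r_rho * dBm * (dph1 * dth1 + dph2 * dth2) + r_rho * dTm * (
                dth1 * dth1 + dth2 * dth2
            )
            S_ph[i, j] = dTm * lap_th
    return u, v, S_om, S_th, S_ph


@njit(cache=True)
def max_abs_diff_scaled(a, b):
    """max|a - b| / max(1, max|a|) in one fused pass."""
    d = 0.0
    m = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            x = abs(a[i, j] - b[i, j])
            if x > d:
                d = x
            y = abs(a[i, j])
            if y > m:
                m = y
    if m < 1.0:
        m = 1.0
    return d / m


@njit(cache=True)
def adi_half_x1(f, u, veff, D, S, dt2, dx1, dx2, alo, glo, ahi, ghi):
    """x1-implicit half-step of d f/dt + d(u f)/dx1 + d(veff f)/dx2 = D lap f + S.

    Advection is conservative centred; the x2 flux and diffusion are
    explicit at the current level.  The wall values at both line ends
    obey the linear closures ``f[0, j] = alo[j] f[1, j] + glo[j]`` and
    ``f[-1, j] = ahi[j] f[-2, j] + ghi[j]``, folded into the tridiagonal
    system so the closure holds at the *new* time level (exact flux
    telescoping for conservative closures; ``alo = 0`` with ``glo`` the
    current wall values reproduces fixed walls).  Wall rows of the
    output are updated from the solved closure.  Returns the updated
    field and a flag that is False when any line system lost diagonal
    dominance.
    """
    n1, n2 = f.shape
    out = f.copy()
    m = n1 - 2
    a = np.empty(m)
    b = np.empty(m)
    c = np.empty(m)
    d = np.empty(m)
    r1 = dt2 * D / (dx1 * dx1)
    r2 = dt2 * D / (dx2 * dx2)
    k1 = dt2 / (2.0 * dx1)
    k2 = dt2 / (2.0 * dx2)
    ok = True
    for j in range(1, n2 - 1):
        for i in range(1, n1 - 1):
            ii = i - 1
            a[ii] = -k1 * u[i - 1, j] - r1
            b[ii] = 1.0 + 2.0 * r1
            c[ii] = k1 * u[i + 1, j] - r1
            if abs(a[ii]) + abs(c[ii]) > abs(b[ii]) + 1e-12:
                ok = False
            d[ii] = f[i, j] + (
                -k2 * (veff[i, j + 1] * f[i, j + 1] - veff[i, j - 1] * f[i, j - 1])
                + r2 * (f[i, j + 1] - 2.0 * f[i, j] + f[i, j - 1])
                + dt2 * S[i, j]
            )
        b[0] += a[0] * alo[j]
        d[0] -= a[0] * glo[j]
        b[m - 1] += c[m - 1] * ahi[j]
        d[m - 1] -= c[m - 1] * ghi[j]
        out[1 : n1 - 1, j] = thomas(a, b, c, d)
        out[0, j] = alo[j] * out[1, j] + glo[j]
        out[n1 - 1, j] = ahi[j] * out[n1 - 2, j] + ghi[j]
    return out, ok


@njit(cache=True)
def adi_half_x2(f, u, veff, D, S, dt2, dx1, dx2, alo, glo, ahi, ghi):
    """x2-implicit half-step; mirror image of :func:`adi_half_x1`."""
    n1, n2 = f.shape
    out = f.copy()
    m = n2 - 2
    a = np.empty(m)
    b = np.empty(m)
    c = np.empty(m)
    d = np.empty(m)
    r1 = dt2 * D / (dx1 * dx1)
    r2 = dt2 * D / (dx2 * dx2)
    k1 = dt2 / (2.0 * dx1)
    k2 = dt2 / (2.0 * dx2)
    ok = True
    for i in range(1, n1 - 1):
        for j in range(1, n2 - 1):
            jj = j - 1
            a[jj] = -k2 * veff[i, j - 1] - r2
            b[jj] = 1.0 + 2.0 * r2
            c[jj] = k2 * veff[i, j + 1] - r2
            if abs(a[jj]) + abs(c[jj]) > abs(b[jj]) + 1e-12:
                ok = False
            d[jj] = f[i, j] + (
                -k1 * (u[i + 1, j] * f[i + 1, j] - u[i - 1, j] * f[i - 1, j])
                + r1 * (f[i + 1, j] - 2.0 * f[i, j] + f[i - 1, j])
                + dt2 * S[i, j]
            )
        b[0] += a[0] * alo[i]
        d[0] -= a[0] * glo[i]
        b[m - 1] += c[m - 1] * ahi[i]
        d[m - 1] -= c[m - 1] * ghi[i]
        out[i, 1 : n2 - 1] = thomas(a, b, c, d)
        out[i, 0] = alo[i] * out[i, 1] + glo[i]
        out[i, n2 - 1] = ahi[i] * out[i, n2 - 2] + ghi[i]
    return out, ok
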