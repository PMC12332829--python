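"""Numba kernels: Thomas tridiagonal solver and the implicit time march.

Kept free of Python objects so the genetic-algorithm inversion, which runs
thousands of forward simulations, stays CPU-cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: clamp for the dimensionless overpotential F(E-Ef0)/RT before exponentiation
ARG_CLAMP = 50.0


@njit(cache=False)
def thomas(lower, diag, upper, rhs):
    """Solve a tridiagonal system by the Thomas algorithm (O(n)).

    Returns ``(x, ok)``; ``ok`` is False when a pivot vanishes.
    ``lower``/``upper`` have length n-1 (sub/super-diagonal), ``diag`` and
    ``rhs`` length n.
    """
    n = diag.shape[0]
    x = np.empty(n)
    cp = np.empty(n)
    dp = np.empty(n)
    if abs(diag[0]) < 1e-300:
        return x, False
    cp[0] = upper[0] / diag[0] if n > 1 else 0.0
    dp[0] = rhs[0] / diag[0]
    for j in range(1, n):
        m = diag[j] - lower[j - 1] * cp[j - 1]
        if abs(m) < 1e-300:
            return x, False
        cp[j] = upper[j] / m if j < n - 1 else 0.0
        dp[j] = (rhs[j] - lower[j - 1] * dp[j - 1]) / m
    x[n - 1] = dp[n - 1]
    for j in range(n - 2, -1, -1):
        x[j] = dp[j] - cp[j] * x[j + 1]
    return x, True


@njit(cache=False)
def march_cv(E_sub, n_sub, n_points, dt, dz, D, k0, alpha, f_thermal, E_f0, c_b):
    """Implicit time march of the 1-D diffusion field with Butler-Volmer flux.

    Backward Euler in time, finite volumes in space.  Each substep solves
    the tridiagonal system

      row 0      : conservative half-cell balance at the electrode,
                   (dz/2)(c0 - c0_old)/dt = D(c1 - c0)/dz - J_BV
                   with the Butler-Volmer flux (new-level surface
                   concentration, new-step potential)
                   J_BV = k0*(c0*eA - (c_b - c0)*eB)
      rows 1..n-2: -lam*c[j-1] + (1+2*lam)*c[j] - lam*c[j+1] = c_old[j]
      row n-1    : Dirichlet c = c_b (far field)

    where lam = D*dt/dz^2, eA = exp(-alpha*x), eB = exp((1-alpha)*x) and
    x = clamp(f_thermal*(E - E_f0), +-ARG_CLAMP).

    Returns (flux_rec, c, flux0, fluxL, ok): ``flux_rec`` is the
    Butler-Volmer surface flux (mol cm^-2 s^-1) at the end of each recorded
    step (J_BV > 0 means the oxidized species is being consumed, i.e. a
    cathodic current); ``flux0``/``fluxL`` are the per-substep boundary
    fluxes for species accounting; ``ok`` flags NaN blow-up.
    """
    n_steps = E_sub.shape[0]
    n_rec = n_steps // n_sub
    c = np.full(n_points, c_b)
    flux_rec = np.empty(n_rec)
    flux0 = np.empty(n_steps)
    fluxL = np.empty(n_steps)

    cp = np.empty(n_points)
    dp = np.empty(n_points)
    lam = D * dt / (dz * dz)
    a_int = -lam
    b_int = 1.0 + 2.0 * lam
    storage = 0.5 * dz / dt

    for k in range(n_steps):
        x = f_thermal * (E_sub[k] - E_f0)
        if x > ARG_CLAMP:
            x = ARG_CLAMP
        elif x < -ARG_CLAMP:
            x = -ARG_CLAMP
        eA = np.exp(-alpha * x)
        eB = np.exp((1.0 - alpha) * x)

        b0 = storage + D / dz + k0 * (eA + eB)
        u0 = -D / dz
        r0 = storage * c[0] + k0 * eB * c_b
        cp[0] = u0 / b0
        dp[0] = r0 / b0
        for j in range(1, n_points - 1):
            m = b_int - a_int * cp[j - 1]
            cp[j] = a_int / m
            dp[j] = (c[j] - a_int * dp[j - 1]) / m
        # Dirichlet last row: diag 1, lower 0
        dp[n_points - 1] = c_b
        c[n_points - 1] = c_b
        for j in range(n_points - 2, -1, -1):
            c[j] = dp[j] - cp[j] * c[j + 1]

        flux0[k] = k0 * (c[0] * eA - (c_b - c[0]) * eB)
        fluxL[k] = D * (c[n_points - 1] - c[n_points - 2]) / dz
        if (k + 1) % n_sub == 0:
            flux_rec[(k + 1) // n_sub - 1] = flux0[k]
            if np.isnan(flux0[k]):
                return flux_rec, c, flux0, fluxL, False
    return flux_rec, c, flux0, fluxL, True
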