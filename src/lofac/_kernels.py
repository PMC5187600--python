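"""JIT-compiled inner sweep loops.

These kernels are the performance-critical core of the two solvers.  They
implement exactly the same arithmetic as the pure-Python operations in
:mod:`lofac.energy` (which the test suite cross-checks against brute-force
oracles and against these kernels); statistics are maintained in
numerator/mass form, which is algebraically identical to the closed-form
prototype updates.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TINY = 1e-12


@njit(cache=True, fastmath=False)
def localized_sweep(
    I, u, s1, s2, n1, n2, q1, q2, patch_mean,
    off_y, off_x, band_y, band_x, m,
):
    """One sequential raster-order sweep of the localized model.

    Visits the band pixels in the given order; for each pixel computes the
    candidate membership from the Euler-Lagrange balance aggregated over
    every patch containing the pixel, evaluates the closed-form energy
    change over those same patch centers, and accepts iff the change is
    strictly negative, updating ``u`` and all affected patch statistics
    immediately (Gauss–Seidel style).

    Mutates ``u`` and the statistic maps in place.  Returns
    ``(accepted_count, delta_f_total)``.
    """
    H, W = I.shape
    K = off_y.shape[0]
    accepted = 0
    df_total = 0.0
    for idx in range(band_y.shape[0]):
        p = band_y[idx]
        q = band_x[idx]
        I0 = I[p, q]
        u0 = u[p, q]
        # candidate from the Euler-Lagrange balance aggregated over all
        # patch centers whose footprint contains this pixel
        a = 0.0
        b = 0.0
        for k in range(K):
            y = p + off_y[k]
            x = q + off_x[k]
            if y < 0 or y >= H or x < 0 or x >= W:
                continue
            if s1[y, x] > TINY:
                c1x = n1[y, x] / s1[y, x]
            else:
                c1x = patch_mean[y, x]
            if s2[y, x] > TINY:
                c2x = n2[y, x] / s2[y, x]
            else:
                c2x = patch_mean[y, x]
            a += (I0 - c1x) * (I0 - c1x)
            b += (I0 - c2x) * (I0 - c2x)
        if a == 0.0 and b == 0.0:
            un = 0.5
        elif a == 0.0:
            un = 1.0
        elif b == 0.0:
            un = 0.0
        else:
            un = 1.0 / (1.0 + (a / b) ** (1.0 / (m - 1.0)))
        if un == u0:
            continue
        d1 = un**m - u0**m
        d2 = (1.0 - un) ** m - (1.0 - u0) ** m
        # closed-form energy change over all patch centers containing P
        dF = 0.0
        for k in range(K):
            y = p + off_y[k]
            x = q + off_x[k]
            if y < 0 or y >= H or x < 0 or x >= W:
                continue
            s1x = s1[y, x]
            den1 = s1x + d1
            if s1x > TINY and den1 > TINY:
                c1x = n1[y, x] / s1x
                dF += s1x * d1 / den1 * (I0 - c1x) * (I0 - c1x)
            else:
                a_old = 0.0
                if s1x > TINY:
                    a_old = q1[y, x] - n1[y, x] * n1[y, x] / s1x
                a_new = 0.0
                if den1 > TINY:
                    nn = n1[y, x] + d1 * I0
                    a_new = (q1[y, x] + d1 * I0 * I0) - nn * nn / den1
                dF += a_new - a_old
            s2x = s2[y, x]
            den2 = s2x + d2
            if s2x > TINY and den2 > TINY:
                c2x = n2[y, x] / s2x
                dF += s2x * d2 / den2 * (I0 - c2x) * (I0 - c2x)
            else:
                b_old = 0.0
                if s2x > TINY:
                    b_old = q2[y, x] - n2[y, x] * n2[y, x] / s2x
                b_new = 0.0
                if den2 > TINY:
                    nn = n2[y, x] + d2 * I0
                    b_new = (q2[y, x] + d2 * I0 * I0) - nn * nn / den2
                dF += b_new - b_old
        if dF < 0.0:
            u[p, q] = un
            accepted += 1
            df_total += dF
            for k in range(K):
                y = p + off_y[k]
                x = q + off_x[k]
                if y < 0 or y >= H or x < 0 or x >= W:
                    continue
                s1[y, x] += d1
                n1[y, x] += d1 * I0
                q1[y, x] += d1 * I0 * I0
                s2[y, x] += d2
                n2[y, x] += d2 * I0
                q2[y, x] += d2 * I0 * I0
    return accepted, df_total


@njit(cache=True, fastmath=False)
def feac_sweep(I, u, state, pix_y, pix_x, m, lam1, lam2, mu, gmean):
    """One sequential sweep of the global FEAC baseline.

    ``state`` is the 6-vector ``[S1, N1, Q1, S2, N2, Q2]`` of whole-image
    class statistics, updated in place after each accepted change.  When
    ``mu > 0`` the energy includes ``mu`` times the count of 4-neighbor
    edges crossing the 0.5 threshold, recounted locally per candidate.
    Returns ``(accepted_count, delta_f_total)``.
    """
    H, W = I.shape
    accepted = 0
    df_total = 0.0
    for idx in range(pix_y.shape[0]):
        p = pix_y[idx]
        q = pix_x[idx]
        I0 = I[p, q]
        u0 = u[p, q]
        S1 = state[0]
        N1 = state[1]
        Q1 = state[2]
        S2 = state[3]
        N2 = state[4]
        Q2 = state[5]
        C1 = N1 / S1 if S1 > TINY else gmean
        C2 = N2 / S2 if S2 > TINY else gmean
        a = lam1 * (I0 - C1) * (I0 - C1)
        b = lam2 * (I0 - C2) * (I0 - C2)
        if a == 0.0 and b == 0.0:
            un = 0.5
        elif a == 0.0:
            un = 1.0
        elif b == 0.0:
            un = 0.0
        else:
            un = 1.0 / (1.0 + (a / b) ** (1.0 / (m - 1.0)))
        if un == u0:
            continue
        d1 = un**m - u0**m
        d2 = (1.0 - un) ** m - (1.0 - u0) ** m
        dF = 0.0
        den1 = S1 + d1
        if S1 > TINY and den1 > TINY:
            dF += lam1 * S1 * d1 / den1 * (I0 - C1) * (I0 - C1)
        else:
            a_old = Q1 - N1 * N1 / S1 if S1 > TINY else 0.0
            a_new = 0.0
            if den1 > TINY:
                nn = N1 + d1 * I0
                a_new = (Q1 + d1 * I0 * I0) - nn * nn / den1
            dF += lam1 * (a_new - a_old)
        den2 = S2 + d2
        if S2 > TINY and den2 > TINY:
            dF += lam2 * S2 * d2 / den2 * (I0 - C2) * (I0 - C2)
        else:
            b_old = Q2 - N2 * N2 / S2 if S2 > TINY else 0.0
            b_new = 0.0
            if den2 > TINY:
                nn = N2 + d2 * I0
                b_new = (Q2 + d2 * I0 * I0) - nn * nn / den2
            dF += lam2 * (b_new - b_old)
        if mu > 0.0:
            was_in = u0 > 0.5
            now_in = un > 0.5
            if was_in != now_in:
                dperim = 0
                for t in range(4):
                    if t == 0:
                        y, x = p - 1, q
                    elif t == 1:
                        y, x = p + 1, q
                    elif t == 2:
                        y, x = p, q - 1
                    else:
                        y, x = p, q + 1
                    if y < 0 or y >= H or x < 0 or x >= W:
                        continue
                    nbr_in = u[y, x] > 0.5
                    old_cross = 1 if (was_in != nbr_in) else 0
                    new_cross = 1 if (now_in != nbr_in) else 0
                    dperim += new_cross - old_cross
                dF += mu * dperim
        if dF < 0.0:
            u[p, q] = un
            accepted += 1
            df_total += dF
            state[0] = den1
            state[1] = N1 + d1 * I0
            state[2] = Q1 + d1 * I0 * I0
            state[3] = den2
            state[4] = N2 + d2 * I0
            state[5] = Q2 + d2 * I0 * I0
    return accepted, df_total
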