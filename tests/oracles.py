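"""Brute-force reference implementations used as independent oracles.

Everything here is written as plain double/quadruple loops straight from
the energy definitions, with no shared code with the package internals:
the package's convolution-based statistics, closed-form incremental
updates and energy-change formulas are validated against these.
"""

from __future__ import annotations

import numpy as np


def disc_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def brute_patch_stats(I: np.ndarray, u: np.ndarray, radius: int, m: float):
    """Per-center s1, s2, c1, c2 by direct summation (patch-mean fallback)."""
    H, W = I.shape
    offs = disc_offsets(radius)
    s1 = np.zeros((H, W))
    s2 = np.zeros((H, W))
    c1 = np.zeros((H, W))
    c2 = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            a = b = na = nb = tot = 0.0
            cnt = 0
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < H and 0 <= xx < W:
                    um = u[yy, xx] ** m
                    vm = (1.0 - u[yy, xx]) ** m
                    a += um
                    b += vm
                    na += um * I[yy, xx]
                    nb += vm * I[yy, xx]
                    tot += I[yy, xx]
                    cnt += 1
            pmean = tot / cnt
            s1[y, x] = a
            s2[y, x] = b
            c1[y, x] = na / a if a > 1e-12 else pmean
            c2[y, x] = nb / b if b > 1e-12 else pmean
    return s1, s2, c1, c2


def brute_total_energy(I: np.ndarray, u: np.ndarray, radius: int, m: float) -> float:
    """Quadruple-loop evaluation of the localized patch energy."""
    H, W = I.shape
    offs = disc_offsets(radius)
    _, _, c1, c2 = brute_patch_stats(I, u, radius, m)
    total = 0.0
    for y in range(H):
        for x in range(W):
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < H and 0 <= xx < W:
                    total += u[yy, xx] ** m * (I[yy, xx] - c1[y, x]) ** 2
                    total += (1.0 - u[yy, xx]) ** m * (I[yy, xx] - c2[y, x]) ** 2
    return total
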