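"""Narrow-band sweep optimizer for the localized patch model.

The contour (0.5-level of the membership field) is evolved by sweeping the
pixels of a narrow band around it in raster order.  Each pixel's candidate
membership comes from the Euler-Lagrange balance aggregated over every
patch containing the pixel (see
:func:`lofac.energy.membership_candidate_at`); the candidate is accepted
iff the closed-form total energy change is strictly negative, and every
affected patch's statistics are updated immediately.  The energy therefore decreases monotonically and the
sweep terminates (the energy is bounded below by zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _kernels
from .energy import compute_local_statistics, total_localized_energy
from .image import (
    LocalStatistics,
    ModelParams,
    PatchMask,
    SegmentationResult,
    init_membership,
    make_disc_mask,
)

__all__ = ["NarrowBand", "extract_narrow_band", "sweep_iteration", "segment"]

#: sweeps between full recomputations of the incrementally maintained
#: statistics (guards floating-point accumulation drift)
RESYNC_EVERY = 50


@dataclass
class NarrowBand:
    """Pixels within ``band_width`` (Chebyshev) of the 0.5-contour.

    ``pixels`` is an ``(N, 2)`` array of (row, col) coordinates in raster
    order; every band pixel has a pixel on the opposite side of the 0.5
    threshold within ``band_width``.
    """

    pixels: np.ndarray
    band_width: int

    def __len__(self) -> int:
        return int(self.pixels.shape[0])


def extract_narrow_band(u: np.ndarray, band_width: int) -> NarrowBand:
    """Locate all pixels within ``band_width`` of a 0.5-threshold crossing.

    A uniform field (no contour) yields an empty band, which the solver
    treats as converged/degenerate.
    """
    if band_width < 1:
        raise ValueError(f"band_width must be >= 1, got {band_width}")
    u = np.asarray(u, dtype=np.float64)
    inside = u > 0.5
    if inside.all() or not inside.any():
        return NarrowBand(pixels=np.empty((0, 2), dtype=np.int64), band_width=band_width)
    size = 2 * band_width + 1
    near_in = ndimage.maximum_filter(inside.astype(np.uint8), size=size, mode="constant", cval=0) > 0
    near_out = ndimage.maximum_filter((~inside).astype(np.uint8), size=size, mode="constant", cval=0) > 0
    band = near_in & near_out
    pixels = np.argwhere(band).astype(np.int64)  # raster order
    return NarrowBand(pixels=pixels, band_width=band_width)


def sweep_iteration(
    image: np.ndarray,
    u: np.ndarray,
    stats: LocalStatistics,
    band: NarrowBand,
    params: ModelParams,
    mask: PatchMask | None = None,
) -> tuple[np.ndarray, LocalStatistics, int, float]:
    """One full raster-order sweep of the band (functional interface).

    Returns ``(u_new, stats_new, accepted_count, delta_f_total)`` where
    ``delta_f_total`` is the (non-positive) sum of accepted energy changes,
    exactly ``F_after - F_before``.
    """
    if mask is None:
        mask = make_disc_mask(params.radius)
    u2 = np.asarray(u, dtype=np.float64).copy()
    st = stats.copy()
    off_y, off_x = mask.offsets
    accepted, dft = _kernels.localized_sweep(
        np.asarray(image, dtype=np.float64), u2,
        st.s1, st.s2, st.n1, st.n2, st.q1, st.q2, st.patch_mean,
        off_y, off_x,
        band.pixels[:, 0].copy(), band.pixels[:, 1].copy(),
        float(params.m),
    )
    st.refresh_prototypes()
    return u2, st, int(accepted), float(dft)


def segment(
    image: np.ndarray,
    seeds,
    params: ModelParams | None = None,
) -> SegmentationResult:
    """Run the localized patch-based fuzzy contour evolution.

    Parameters
    ----------
    image : ndarray
        Gray image on [0, 1].
    seeds : list of (top, left, height, width) rectangles or boolean mask
        Initial interior; the initial membership is crisp 1 inside / 0
        outside.
    params : ModelParams, optional
        Model and optimizer parameters (defaults: radius 20, m 2,
        band_width 2, 200 sweeps max).

    Returns
    -------
    SegmentationResult
        Final membership, non-increasing energy trace (one entry per sweep
        plus the initial energy), sweep count and convergence flag.
    """
    if params is None:
        params = ModelParams()
    image = np.asarray(image, dtype=np.float64)
    u = init_membership(image, seeds)
    mask = make_disc_mask(params.radius)
    off_y, off_x = mask.offsets
    stats = compute_local_statistics(image, u, mask, params.m)
    f0 = total_localized_energy(image, u, stats, mask, params.m)
    trace = [f0]
    f_current = f0
    converged = False
    iterations = 0
    for sweep in range(params.max_iterations):
        band = extract_narrow_band(u, params.band_width)
        if len(band) == 0:
            if sweep == 0:
                warnings.warn(
                    "initial membership has no 0.5-contour; returning the "
                    "initial partition", stacklevel=2)
            converged = True
            break
        accepted, dft = _kernels.localized_sweep(
            image, u,
            stats.s1, stats.s2, stats.n1, stats.n2, stats.q1, stats.q2,
            stats.patch_mean,
            off_y, off_x,
            band.pixels[:, 0].copy(), band.pixels[:, 1].copy(),
            float(params.m),
        )
        iterations = sweep + 1
        f_current += dft
        trace.append(f_current)
        if accepted == 0:
            converged = True
            break
        if abs(dft) < params.energy_tolerance * max(abs(f0), 1e-300):
            converged = True
            break
        if (sweep + 1) % RESYNC_EVERY == 0:
            stats = compute_local_statistics(image, u, mask, params.m)
    stats.refresh_prototypes()
    return SegmentationResult(
        membership=u,
        energy_trace=np.asarray(trace, dtype=np.float64),
        iterations_run=iterations,
        converged=converged,
    )
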