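"""Core domain types, coordinate conventions and image/mask I/O.

Conventions used throughout the package:

* Images and membership maps are dense 2-D ``float64`` arrays indexed
  ``(row, col)``, 0-based.
* A *gray image* has intensities min–max normalized to ``[0, 1]``.
* A *membership map* ``u`` has values in ``[0, 1]``; the evolving contour is
  the 0.5-level of ``u``, the foreground ("inside") is ``u > 0.5`` and the
  background ("outside") is ``u < 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PatchMask",
    "ModelParams",
    "LocalStatistics",
    "SegmentationResult",
    "load_image",
    "as_gray_image",
    "make_disc_mask",
    "init_membership",
    "save_mask_png",
    "load_mask_png",
    "save_membership_png",
    "save_membership_txt",
    "load_membership_txt",
]

#: numerical floor below which a fuzzy class weight is treated as empty
TINY = 1e-12


@dataclass(frozen=True)
class PatchMask:
    """Binary disc footprint selecting the local patch around each pixel.

    The patch of radius ``r`` centered at ``x`` contains every pixel ``y``
    with Euclidean distance ``|y - x| <= r``; the footprint stores the
    corresponding ``(2r+1, 2r+1)`` boolean stencil of offsets.
    """

    radius: int
    footprint: np.ndarray = field(repr=False)

    @property
    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col offset arrays of the footprint's True entries."""
        dy, dx = np.nonzero(self.footprint)
        return dy - self.radius, dx - self.radius

    @property
    def size(self) -> int:
        return int(self.footprint.sum())


def make_disc_mask(radius: int) -> PatchMask:
    """Build the disc patch footprint of the given integer radius.

    Raises
    ------
    ValueError
        If ``radius < 1`` or radius is not integral.
    """
    if radius != int(radius):
        raise ValueError(f"radius must be an integer, got {radius!r}")
    radius = int(radius)
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    footprint = (dy * dy + dx * dx) <= radius * radius
    footprint.setflags(write=False)
    return PatchMask(radius=radius, footprint=footprint)


@dataclass
class ModelParams:
    """Parameters of the localized patch model and its optimizer.

    Attributes
    ----------
    radius : int
        Localization radius ``r`` in pixels; sets the scale of the local
        statistics. Default 20.
    m : float
        Fuzzifier exponent weighting memberships in the energy; must be > 1
        (the membership closed form divides by ``m - 1``). Default 2.
    max_iterations : int
        Hard cap on the number of full narrow-band sweeps. Default 200.
    band_width : int
        Chebyshev half-width of the narrow band around the 0.5-contour.
        Default 1: the contour still moves one pixel per sweep, and the
        tight band keeps noise-induced membership flips from chaining away
        from the contour (a wider band lets isolated noisy pixels near the
        front become updatable and degrades robustness).
    energy_tolerance : float
        Relative convergence tolerance: a sweep whose total accepted energy
        decrease is below ``energy_tolerance * F_initial`` stops the solver.
    model : str
        ``"localized"`` (patch model) or ``"feac"`` (global baseline).
    """

    radius: int = 20
    m: float = 2.0
    max_iterations: int = 200
    band_width: int = 1
    energy_tolerance: float = 1e-10
    model: str = "localized"

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.band_width < 1:
            raise ValueError(f"band_width must be >= 1, got {self.band_width}")
        if self.model not in ("localized", "feac"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class LocalStatistics:
    """Per-patch-center maps of the fuzzy class statistics.

    For every pixel ``x`` (as patch center), with ``W`` the disc footprint
    clipped to the image:

    * ``s1(x) = sum_y W(x,y) u(y)^m`` — fuzzy foreground mass of the patch,
    * ``s2(x) = sum_y W(x,y) (1-u(y))^m`` — fuzzy background mass,
    * ``c1(x)``, ``c2(x)`` — membership-weighted mean intensities (local
      prototypes) of the two classes.

    Where a class is empty (``s`` below :data:`TINY`) the prototype falls
    back to the unweighted patch mean, which keeps the membership closed
    form evaluable; the class carries zero weight in the energy so any
    finite value is energetically equivalent.

    The numerators ``n1 = sum W u^m I``, ``n2`` and second moments
    ``q1 = sum W u^m I^2``, ``q2`` are kept alongside: they make the
    incremental updates exact and give a direct per-patch energy
    ``A1(x) = q1 - n1^2/s1`` used as a fallback for degenerate patches.
    """

    s1: np.ndarray
    s2: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    patch_mean: np.ndarray
    patch_count: np.ndarray

    def copy(self) -> "LocalStatistics":
        return LocalStatistics(
            **{k: getattr(self, k).copy() for k in (
                "s1", "s2", "c1", "c2", "n1", "n2", "q1", "q2",
                "patch_mean", "patch_count")}
        )

    def refresh_prototypes(self) -> None:
        """Recompute c1/c2 from the maintained numerators and masses."""
        self.c1 = np.where(self.s1 > TINY, self.n1 / np.where(self.s1 > TINY, self.s1, 1.0), self.patch_mean)
        self.c2 = np.where(self.s2 > TINY, self.n2 / np.where(self.s2 > TINY, self.s2, 1.0), self.patch_mean)


@dataclass
class SegmentationResult:
    """Outcome of a contour evolution run.

    ``energy_trace[k]`` is the total energy after sweep ``k`` (entry 0 is
    the initial energy); accepted updates strictly decrease it, so the
    trace is non-increasing.
    """

    membership: np.ndarray
    energy_trace: np.ndarray
    iterations_run: int
    converged: bool

    @property
    def binary_mask(self) -> np.ndarray:
        """Foreground mask, exactly ``membership > 0.5``."""
        return self.membership > 0.5


# ---------------------------------------------------------------------------
# image loading / normalization


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Normalize an array to a float64 gray image on [0, 1].

    RGB(A) input is converted to gray by channel mean (alpha dropped);
    intensities are min–max scaled. A constant image maps to all zeros.
    """
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 3:
        a = a[..., :3].mean(axis=2)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D (or RGB) image, got shape {a.shape}")
    if a.size == 0:
        raise ValueError("zero-sized image")
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        a = (a - lo) / (hi - lo)
    else:
        a = np.zeros_like(a)
    return a


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF/PGM raster as a normalized gray image.

    8- and 16-bit single-channel and RGB images are supported; RGB is
    converted by luminance (channel) average before normalization.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        raw = iio.imread(str(path))
    return as_gray_image(raw)


# ---------------------------------------------------------------------------
# initial membership


RectLike = Sequence[int]  # (top, left, height, width)


def init_membership(
    image: np.ndarray,
    seeds: Sequence[RectLike] | np.ndarray,
    u_in: float = 1.0,
    u_out: float = 0.0,
) -> np.ndarray:
    """Build the initial membership map from seed rectangles or a mask.

    The initial partition only needs ``u > 0.5`` inside the seeds and
    ``u < 0.5`` outside; the crisp defaults 1/0 are used.

    Parameters
    ----------
    image : ndarray
        The gray image (only its shape is used).
    seeds : list of (top, left, height, width) rectangles, or boolean mask
        Seed region(s). Multiple (possibly disjoint) rectangles are
        supported; their union is the initial interior.
    """
    if not (u_out < 0.5 < u_in):
        raise ValueError("need u_out < 0.5 < u_in")
    shape = np.asarray(image).shape[:2]
    u = np.full(shape, u_out, dtype=np.float64)
    if isinstance(seeds, np.ndarray) and seeds.dtype == bool:
        if seeds.shape != shape:
            raise ValueError(f"seed mask shape {seeds.shape} != image shape {shape}")
        if not seeds.any():
            raise ValueError("empty seed mask")
        u[seeds] = u_in
        return u
    seeds = list(seeds)
    if len(seeds) == 0:
        raise ValueError("empty seed set")
    H, W = shape
    for rect in seeds:
        top, left, h, w = (int(v) for v in rect)
        if h <= 0 or w <= 0:
            raise ValueError(f"rectangle {rect!r} has non-positive size")
        if top < 0 or left < 0 or top + h > H or left + w > W:
            raise ValueError(f"rectangle {rect!r} out of bounds for {H}x{W} image")
        u[top : top + h, left : left + w] = u_in
    return u


# ---------------------------------------------------------------------------
# writers / readers


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    import imageio.v3 as iio

    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(str(path), out)


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG back as a boolean array (nonzero = True)."""
    import imageio.v3 as iio

    raw = iio.imread(str(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > 0


def save_membership_png(u: np.ndarray, path: str | Path) -> None:
    """Write a membership map as an 8-bit PNG, scaled 0–255 (lossy)."""
    import imageio.v3 as iio

    out = np.clip(np.round(np.asarray(u, dtype=np.float64) * 255.0), 0, 255)
    iio.imwrite(str(path), out.astype(np.uint8))


def save_membership_txt(u: np.ndarray, path: str | Path) -> None:
    """Lossless textual dump of a membership map (one row per line)."""
    np.savetxt(str(path), np.asarray(u, dtype=np.float64), fmt="%.17g")


def load_membership_txt(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(str(path), dtype=np.float64, ndmin=2)
    return arr
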