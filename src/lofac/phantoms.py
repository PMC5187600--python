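"""Seedable synthetic phantom generator with ground-truth masks.

The presets reproduce the statistical structure of the validation
experiments the package targets:

* :func:`three_object_phantom` — three objects with distinct intensity
  levels and interior holes on a dark background (multi-object extraction;
  the dimmest object is deliberately close to the background so a global
  two-prototype model drops it).
* :func:`circle_rectangle_phantom` — a circle and a rectangle corrupted by
  additive Gaussian noise of configurable variance (noise robustness).
* :func:`inhomogeneous_phantom` — two elongated bars whose intensity ramps
  along their axis and overlaps the background's intensity range, plus a
  smooth multiplicative bias field: the regime where global energies fail
  and localization is required.

Ground-truth masks are rendered noise- and bias-free by construction, and
every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "Shape",
    "PhantomSpec",
    "generate_phantom",
    "three_object_spec",
    "three_object_phantom",
    "circle_rectangle_spec",
    "circle_rectangle_phantom",
    "inhomogeneous_spec",
    "inhomogeneous_phantom",
    "default_seed_box",
]

Level = Union[float, tuple]  # constant, or (top, bottom) vertical linear ramp


@dataclass(frozen=True)
class Shape:
    """One phantom shape: a circle, rectangle or annulus at an intensity level.

    ``level`` is either a constant on [0, 1] or a ``(top, bottom)`` pair
    interpreted as a linear ramp over the image rows (evaluated on the
    shape's support).  ``holes`` are circles ``(cy, cx, r)`` subtracted
    from the support; hole pixels revert to background in the image and
    are background in the ground truth.
    """

    kind: str  # "circle" | "rectangle" | "annulus"
    level: Level
    center: tuple[int, int] | None = None
    radius: float | None = None
    inner_radius: float | None = None
    rect: tuple[int, int, int, int] | None = None  # (top, left, height, width)
    holes: tuple = ()
    #: distractor structures (clutter) are rendered in the image but are
    #: not part of the segmentation target, hence excluded from the truth
    foreground: bool = True

    def support(self, H: int, W: int) -> np.ndarray:
        yy, xx = np.mgrid[0:H, 0:W]
        if self.kind == "circle" or self.kind == "annulus":
            cy, cx = self.center
            r = float(self.radius)
            if cy - r < 0 or cy + r > H - 1 or cx - r < 0 or cx + r > W - 1:
                raise ValueError(f"{self.kind} at {self.center} r={r} outside {H}x{W} canvas")
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            sup = d2 <= r * r
            if self.kind == "annulus":
                ri = float(self.inner_radius)
                if not 0 < ri < r:
                    raise ValueError("annulus needs 0 < inner_radius < radius")
                sup &= d2 > ri * ri
        elif self.kind == "rectangle":
            top, left, h, w = self.rect
            if top < 0 or left < 0 or top + h > H or left + w > W:
                raise ValueError(f"rectangle {self.rect} outside {H}x{W} canvas")
            sup = (yy >= top) & (yy < top + h) & (xx >= left) & (xx < left + w)
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        for cy, cx, r in self.holes:
            sup &= (yy - cy) ** 2 + (xx - cx) ** 2 > r * r
        return sup


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom.

    ``bias_amplitude``/``bias_scale`` parameterize a smooth multiplicative
    bias field ``1 + a*(2*exp(-d^2/(2*scale^2)) - 1)`` (a broad radial
    bump spanning ``[1-a, 1+a]``, ``d`` the distance to ``bias_center``).
    ``noise_variance`` is the variance of additive Gaussian noise on the
    [0, 1] intensity scale; the noisy image is clipped back to [0, 1].
    """

    height: int
    width: int
    shapes: tuple = ()
    background_level: Level = 0.1
    bias_amplitude: float = 0.0
    bias_scale: float | None = None
    bias_center: tuple[float, float] | None = None
    noise_variance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom must be at least 1x1")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


def _level_field(level: Level, H: int, W: int) -> np.ndarray:
    if isinstance(level, tuple):
        top, bottom = level
        col = np.linspace(float(top), float(bottom), H)[:, None]
        return np.broadcast_to(col, (H, W)).copy()
    return np.full((H, W), float(level))


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom: returns ``(image, ground_truth_mask)``.

    Shapes are painted in order over the background, the bias field is
    applied multiplicatively, Gaussian noise is added and the image is
    clipped to [0, 1].  The ground truth (union of shape supports minus
    holes) is unaffected by bias and noise.  Deterministic given the seed.
    """
    H, W = spec.height, spec.width
    img = _level_field(spec.background_level, H, W)
    truth = np.zeros((H, W), dtype=bool)
    for shape in spec.shapes:
        sup = shape.support(H, W)
        img[sup] = _level_field(shape.level, H, W)[sup]
        if shape.foreground:
            truth |= sup
    if spec.bias_amplitude != 0.0:
        cy, cx = spec.bias_center if spec.bias_center is not None else ((H - 1) / 2.0, (W - 1) / 2.0)
        scale = spec.bias_scale if spec.bias_scale is not None else max(H, W) / 2.0
        yy, xx = np.mgrid[0:H, 0:W]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img *= 1.0 + spec.bias_amplitude * (2.0 * np.exp(-d2 / (2.0 * scale**2)) - 1.0)
    if spec.noise_variance > 0.0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, np.sqrt(spec.noise_variance), size=(H, W))
    return np.clip(img, 0.0, 1.0), truth


def default_seed_box(size: int, margin: int = 14) -> list[tuple[int, int, int, int]]:
    """Single seed rectangle leaving ``margin`` pixels to the image border."""
    return [(margin, margin, size - 2 * margin, size - 2 * margin)]


def seed_boxes_for(spec: PhantomSpec, margin: int = 5) -> list[tuple[int, int, int, int]]:
    """Per-shape seed rectangles: each shape's bounding box grown by ``margin``.

    Localized region statistics carry information only within the patch
    radius, so the standard initialization places the initial contour(s)
    near the objects; a box around each shape (as with the two-rectangle
    initializations of multi-object figures) keeps every traversed
    background pixel within the patches' reach.
    """
    H, W = spec.height, spec.width
    boxes = []
    for shape in spec.shapes:
        if shape.kind in ("circle", "annulus"):
            cy, cx = shape.center
            r = int(np.ceil(shape.radius))
            top, left = cy - r, cx - r
            h = w = 2 * r + 1
        else:
            top, left, h, w = shape.rect
        top = max(top - margin, 0)
        left = max(left - margin, 0)
        bot = min(top + h + 2 * margin, H)
        right = min(left + w + 2 * margin, W)
        boxes.append((top, left, bot - top, right - left))
    return boxes


# ---------------------------------------------------------------------------
# presets


def three_object_spec(seed: int = 0, size: int = 128) -> PhantomSpec:
    """Three objects with pairwise-distinct levels (gaps >= 0.15) and holes.

    A bright circle with two holes, a mid-level circle with one hole, and a
    deliberately dim wide rectangle whose level sits close above the
    background — locally separable everywhere, but expendable to a global
    two-prototype fit.
    """
    t = size / 128.0

    def s(v: float) -> int:
        return int(round(v * t))

    shapes = (
        Shape("circle", level=0.95, center=(s(38), s(42)), radius=s(17),
              holes=((s(33), s(37), s(3)), (s(44), s(48), s(3)))),
        Shape("circle", level=0.60, center=(s(40), s(88)), radius=s(17),
              holes=((s(40), s(88), s(4)),)),
        Shape("rectangle", level=0.30, rect=(s(76), s(34), s(29), s(61))),
    )
    return PhantomSpec(height=size, width=size, shapes=shapes,
                       background_level=0.05, seed=seed)


def three_object_phantom(seed: int = 0, size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Render the three-object preset; returns ``(image, truth)``."""
    return generate_phantom(three_object_spec(seed, size))


def circle_rectangle_spec(
    noise_variance: float = 0.0, seed: int = 0, size: int = 128
) -> PhantomSpec:
    """A circle and a rectangle (level 0.95 on background 0.05) plus noise.

    The shapes dominate the frame, as in the noise-robustness figures; the
    standard initialization is :func:`seed_boxes_for` (one box per shape).
    """
    t = size / 128.0

    def s(v: float) -> int:
        return int(round(v * t))

    shapes = (
        Shape("circle", level=0.95, center=(s(40), s(42)), radius=s(32)),
        Shape("rectangle", level=0.95, rect=(s(78), s(50), s(42), s(68))),
    )
    return PhantomSpec(height=size, width=size, shapes=shapes,
                       background_level=0.05,
                       noise_variance=noise_variance, seed=seed)


def circle_rectangle_phantom(
    noise_variance: float = 0.0, seed: int = 0, size: int = 128
) -> tuple[np.ndarray, np.ndarray]:
    """Render the circle+rectangle preset; returns ``(image, truth)``."""
    return generate_phantom(circle_rectangle_spec(noise_variance, seed, size))


def inhomogeneous_spec(seed: int = 0, size: int = 128) -> PhantomSpec:
    """Two elongated bars with axial intensity ramps, plus bright clutter.

    The background ramps from 0.05 (top) to 0.55 (bottom); the two target
    bars ramp from 0.35 to 0.85 over the same rows, keeping a constant
    local contrast of 0.3 while the global histograms overlap, so no
    single threshold separates object from background.  Two bright
    distractor strips hug the left and right image borders (rendered, but
    not part of the ground truth — the clutter next to the objects of
    interest): a localization radius large enough to pull them into the
    patches corrupts the local background prototype at the bar boundaries
    ("too global"), while a radius smaller than half the inter-bar gap
    cannot carry boundary information across the gap ("too local").  A
    smooth multiplicative bias field (amplitude 0.15) adds large-scale
    distortion.
    """
    t = size / 128.0

    def s(v: float) -> int:
        return int(round(v * t))

    bar_level = (0.35, 0.85)
    shapes = (
        Shape("rectangle", level=bar_level, rect=(s(14), s(22), s(100), s(17))),
        Shape("rectangle", level=bar_level, rect=(s(14), s(90), s(100), s(17))),
        Shape("rectangle", level=0.9, rect=(s(6), 0, s(116), s(10)), foreground=False),
        Shape("rectangle", level=0.9, rect=(s(6), size - s(10), s(116), s(10)), foreground=False),
    )
    return PhantomSpec(height=size, width=size, shapes=shapes,
                       background_level=(0.05, 0.55),
                       bias_amplitude=0.15, bias_scale=60.0 * t,
                       seed=seed)


def inhomogeneous_seed_box(size: int = 128) -> list[tuple[int, int, int, int]]:
    """Standard single-rectangle initialization for the inhomogeneity preset.

    The box covers both bars and the gap between them, hugs the bars on
    the outer sides (2 px) and excludes the border clutter, so the initial
    contour starts close to the target boundaries everywhere except inside
    the wide inter-bar gap — the transit that a too-small radius cannot
    negotiate.
    """
    t = size / 128.0

    def s(v: float) -> int:
        return int(round(v * t))

    return [(s(12), s(20), s(104), s(88))]


def inhomogeneous_phantom(seed: int = 0, size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Render the intensity-inhomogeneity preset; returns ``(image, truth)``."""
    return generate_phantom(inhomogeneous_spec(seed, size))
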