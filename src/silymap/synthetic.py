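"""Seeded synthetic multispectral scenes with patchy two-class ground truth.

The generator emulates the statistical structure of an uncultivated field in
which vigorous milk thistle (*Silybum marianum*, class 1) grows in large
contiguous patches among drying graminaceous vegetation (class 2):

* the target class has higher near-infrared reflectance (vigorous canopy),
* the target class carries extra high-frequency NIR variation, so its 7x7
  local variance ("texture") is stochastically larger,
* green and red reflectances are nearly identical between the classes, so
  those bands are uninformative by construction.

All randomness flows from one master seed; each operation draws from a child
stream derived from a fixed integer label, so adding an operation never
perturbs the streams of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassMap",
    "SpectralScene",
    "PolygonSet",
    "Rectangle",
    "SceneParams",
    "generate_class_map",
    "generate_scene",
    "generate_polygons",
]

TARGET = 1  # S. marianum
OTHER = 2  # other vegetation

# fixed child-stream labels (RNG contract: master seed + operation label)
_STREAM_CLASS_MAP = 101
_STREAM_SCENE = 102
_STREAM_POLYGONS = 103

BAND_NAMES = ("green", "red", "nir")


class SceneSizingError(ValueError):
    """Raised for degenerate grid dimensions or shape mismatches."""


class PolygonPlacementError(RuntimeError):
    """Raised when the requested rectangles cannot be placed in pure-class area."""


@dataclass(frozen=True)
class ClassMap:
    """Per-pixel ground truth: 1 = target weed, 2 = other vegetation."""

    labels: np.ndarray
    pixel_size: float = 0.5  # ground units per pixel; metadata only

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise SceneSizingError("class map must be a 2-D grid")
        if not np.isin(labels, (TARGET, OTHER)).all():
            raise ValueError("class codes must be 1 (target) or 2 (other)")
        object.__setattr__(self, "labels", labels.astype(np.int16, copy=False))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def coverage(self) -> float:
        """Areal fraction occupied by the target class."""
        return float(np.mean(self.labels == TARGET))


@dataclass(frozen=True)
class SpectralScene:
    """Three co-registered reflectance grids (green, red, NIR) plus validity mask."""

    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        bands = [np.asarray(b, dtype=float) for b in (self.green, self.red, self.nir)]
        shapes = {b.shape for b in bands}
        if len(shapes) != 1 or bands[0].ndim != 2:
            raise SceneSizingError("all bands must share one 2-D shape")
        for name, b in zip(BAND_NAMES, bands):
            if not np.isfinite(b).all() or (b < 0).any():
                raise ValueError(f"{name} band must be finite and non-negative")
        mask = self.mask
        if mask is None:
            mask = np.ones(bands[0].shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != bands[0].shape:
                raise SceneSizingError("mask shape must match the bands")
        object.__setattr__(self, "green", bands[0])
        object.__setattr__(self, "red", bands[1])
        object.__setattr__(self, "nir", bands[2])
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    def bands(self) -> dict[str, np.ndarray]:
        return {"green": self.green, "red": self.red, "nir": self.nir}


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int
    class_code: int

    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.mgrid[self.row0 : self.row1, self.col0 : self.col1]
        return rr.ravel(), cc.ravel()

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def intersects(self, other: "Rectangle") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )


@dataclass(frozen=True)
class PolygonSet:
    """Labeled sampling rectangles, each pure in its own ground-truth class."""

    polygons: tuple[Rectangle, ...]

    def count(self, class_code: int) -> int:
        return sum(1 for p in self.polygons if p.class_code == class_code)

    @property
    def counts(self) -> dict[int, int]:
        return {TARGET: self.count(TARGET), OTHER: self.count(OTHER)}


@dataclass(frozen=True)
class SceneParams:
    """Reflectance model for the two vegetation classes.

    Means are unitless reflectances in [0, 1]. ``noise_sd`` is the standard
    deviation of the spatially smooth within-class variation of each band.
    ``texture_contrast`` is the amplitude of independent per-pixel noise added
    to the NIR band inside target patches only, which is what makes the local
    variance layer discriminative. Green and red means are deliberately equal
    between classes: the two canopies look alike in the visible bands.
    """

    mean_target: dict[str, float] = field(
        default_factory=lambda: {"green": 0.12, "red": 0.10, "nir": 0.50}
    )
    mean_other: dict[str, float] = field(
        default_factory=lambda: {"green": 0.12, "red": 0.10, "nir": 0.35}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"green": 0.002, "red": 0.002, "nir": 0.03}
    )
    pixel_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"green": 0.015, "red": 0.015, "nir": 0.035}
    )
    texture_contrast: float = 0.06
    noise_scale: float = 4.0  # smoothing length of the within-class noise field
    seed: int = 0

    def __post_init__(self) -> None:
        for name in BAND_NAMES:
            if self.noise_sd[name] < 0 or self.pixel_noise_sd[name] < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be >= 0")


def _smooth_unit_field(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to zero mean, unit variance."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="reflect")
    sd = field_.std()
    if sd == 0:  # scale=0 with degenerate RNG draw; keep the raw field
        return field_
    return (field_ - field_.mean()) / sd


def generate_class_map(
    height: int,
    width: int,
    patch_scale: float,
    coverage_fraction: float,
    seed: int,
) -> ClassMap:
    """Patchy two-class ground truth with exact target coverage.

    A smooth random field (white noise convolved with an isotropic Gaussian of
    length ``patch_scale``) is thresholded at its empirical
    ``1 - coverage_fraction`` quantile, so the target class occupies
    ``coverage_fraction`` of the cells up to quantile granularity.
    """
    if not (0.0 < coverage_fraction < 1.0):
        raise ValueError("coverage_fraction must lie in (0, 1)")
    if height < 4 * patch_scale or width < 4 * patch_scale:
        raise SceneSizingError(
            f"grid {height}x{width} too small for patch_scale={patch_scale}; "
            "need height, width >= 4*patch_scale"
        )
    rng = np.random.default_rng([seed, _STREAM_CLASS_MAP])
    field_ = _smooth_unit_field((height, width), patch_scale, rng)
    threshold = np.quantile(field_, 1.0 - coverage_fraction)
    labels = np.where(field_ > threshold, TARGET, OTHER)
    # the quantile cell itself is ties-to-other; with a continuous field the
    # realized coverage is within 1/(H*W) of the request
    return ClassMap(labels=labels)


def generate_scene(class_map: ClassMap, params: SceneParams) -> SpectralScene:
    """Render reflectance bands over a class map.

    Each band is the per-class mean, plus smooth within-class variation,
    plus per-pixel sensor noise, all shared by both classes. The target
    class's NIR cells additionally carry independent high-frequency noise of
    amplitude ``texture_contrast`` (rough canopy of large discrete plants),
    so the 7x7 local variance of NIR is stochastically larger inside target
    patches; green/red class means coincide, so those bands separate the
    classes only by chance.
    """
    rng = np.random.default_rng([params.seed, _STREAM_SCENE])
    labels = class_map.labels
    target_mask = labels == TARGET
    bands: dict[str, np.ndarray] = {}
    for name in BAND_NAMES:
        mean = np.where(target_mask, params.mean_target[name], params.mean_other[name])
        sd = params.noise_sd[name]
        band = mean.astype(float)
        if sd > 0:
            band = band + sd * _smooth_unit_field(labels.shape, params.noise_scale, rng)
        px_sd = params.pixel_noise_sd[name]
        if px_sd > 0:
            band = band + px_sd * rng.standard_normal(labels.shape)
        if name == "nir" and params.texture_contrast > 0:
            speckle = rng.standard_normal(labels.shape) * params.texture_contrast
            band = band + np.where(target_mask, speckle, 0.0)
        bands[name] = np.clip(band, 0.0, None)
    return SpectralScene(green=bands["green"], red=bands["red"], nir=bands["nir"])


def _pure_placements(labels: np.ndarray, class_code: int, rect_h: int, rect_w: int) -> np.ndarray:
    """Top-left corners (r, c) where a rect_h x rect_w box is entirely class_code."""
    pure = (labels == class_code).astype(np.int64)
    h, w = labels.shape
    if rect_h > h or rect_w > w:
        return np.empty((0, 2), dtype=int)
    # integral image: box sums over all anchor positions at once
    csum = np.cumsum(np.cumsum(np.pad(pure, ((1, 0), (1, 0))), axis=0), axis=1)
    box = (
        csum[rect_h : h + 1, rect_w : w + 1]
        - csum[0 : h - rect_h + 1, rect_w : w + 1]
        - csum[rect_h : h + 1, 0 : w - rect_w + 1]
        + csum[0 : h - rect_h + 1, 0 : w - rect_w + 1]
    )
    rows, cols = np.nonzero(box == rect_h * rect_w)
    return np.stack([rows, cols], axis=1)


def generate_polygons(
    class_map: ClassMap,
    n_per_class: tuple[int, int],
    rect_size: tuple[int, int] | int = 8,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> PolygonSet:
    """Place disjoint pure-class sampling rectangles, n_per_class = (target, other).

    Rectangles are drawn uniformly from the set of fully-pure anchor positions
    of each class and accepted greedily if disjoint from all earlier ones.
    Deterministic for a fixed seed.
    """
    if isinstance(rect_size, int):
        rect_size = (rect_size, rect_size)
    rect_h, rect_w = rect_size
    if rect_h < 1 or rect_w < 1:
        raise SceneSizingError("rectangle sides must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_POLYGONS])
    placed: list[Rectangle] = []
    class_names = {TARGET: "target weed", OTHER: "other vegetation"}
    for class_code, wanted in ((TARGET, n_per_class[0]), (OTHER, n_per_class[1])):
        anchors = _pure_placements(class_map.labels, class_code, rect_h, rect_w)
        if len(anchors) < wanted:
            raise PolygonPlacementError(
                f"not enough pure-class area for class '{class_names[class_code]}': "
                f"{len(anchors)} candidate positions for {wanted} rectangles"
            )
        order = rng.permutation(len(anchors))
        got = 0
        for idx in order[: max_attempts]:
            r, c = anchors[idx]
            rect = Rectangle(int(r), int(c), int(r + rect_h), int(c + rect_w), class_code)
            if all(not rect.intersects(p) for p in placed):
                placed.append(rect)
                got += 1
                if got == wanted:
                    break
        if got < wanted:
            raise PolygonPlacementError(
                f"could not place {wanted} disjoint rectangles for class "
                f"'{class_names[class_code]}' (placed {got})"
            )
    return PolygonSet(polygons=tuple(placed))
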