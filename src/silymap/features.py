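"""Feature preparation: texture layer, feature stack, pixel sampling, splits.

The classifier input for every pixel is a four-vector in fixed storage order
(green, red, nir, texture) where texture is the 7x7 local variance of the NIR
band — a structural-roughness measure: tall discrete weed plants give a rough
canopy (high local variance), a flat graminaceous sward a smooth one.

Labeled pixels are harvested from sampling rectangles, the class counts are
balanced by seeded undersampling of the majority class, and the balanced pool
is split 70/30 into calibration and validation sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import TARGET, PolygonSet, SceneSizingError, SpectralScene

__all__ = [
    "FEATURE_NAMES",
    "FeatureStack",
    "PixelDataset",
    "StandardizationParams",
    "local_variance",
    "build_feature_stack",
    "sample_pixels",
    "balance_calibration",
    "split_train_validation",
    "fit_standardization",
    "apply_standardization",
    "block_mean_resample",
]

logger = logging.getLogger(__name__)

# storage order of the input features; reports may display them differently
FEATURE_NAMES = ("green", "red", "nir", "texture")

_STREAM_BALANCE = 201
_STREAM_SPLIT = 202

_SCALE_FLOOR = 1e-8


class DatasetCompositionError(ValueError):
    """Raised when a dataset lacks a class required by the operation."""


def local_variance(band: np.ndarray, window_size: int = 7) -> np.ndarray:
    """Per-pixel population variance of a square moving window.

    Each output cell is the divide-by-count variance of the
    ``window_size x window_size`` neighborhood centered on it; edges use the
    reflect-padded neighborhood, so the output has the input's shape.
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError("window_size must be odd and >= 3")
    band = np.asarray(band, dtype=np.float64)
    if not np.isfinite(band).all():
        raise ValueError("band must be finite")
    # center first: Var(x) = E[(x-c)^2] - E[x-c]^2 is exact for any c, and
    # removing the global mean avoids cancellation between E[x^2] and E[x]^2
    centered = band - band.mean()
    mean = ndimage.uniform_filter(centered, size=window_size, mode="reflect")
    mean_sq = ndimage.uniform_filter(centered * centered, size=window_size, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


@dataclass(frozen=True)
class FeatureStack:
    """Four same-shape layers in storage order (green, red, nir, texture)."""

    layers: np.ndarray  # (4, H, W)
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        layers = np.asarray(self.layers, dtype=float)
        if layers.ndim != 3 or layers.shape[0] != len(FEATURE_NAMES):
            raise SceneSizingError("feature stack must have shape (4, H, W)")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != layers.shape[1:]:
            raise SceneSizingError("mask shape must match layer shape")
        if not np.isfinite(layers[:, mask]).all():
            raise ValueError("features must be finite where the mask is true")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "mask", mask)

    @property
    def n(self) -> int:
        return self.layers.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        return self.layers[FEATURE_NAMES.index(name)]

    def pixel_matrix(self) -> np.ndarray:
        """All pixels as an (H*W, n) matrix in row-major pixel order."""
        return self.layers.reshape(self.n, -1).T


def build_feature_stack(scene: SpectralScene, window_size: int = 7) -> FeatureStack:
    """Stack (green, red, nir, texture) with texture = local variance of NIR."""
    texture = local_variance(scene.nir, window_size)
    layers = np.stack([scene.green, scene.red, scene.nir, texture])
    return FeatureStack(layers=layers, mask=scene.mask)


@dataclass(frozen=True)
class PixelDataset:
    """Labeled pixel sample: features x_i, binary targets t_i, provenance coords.

    Labels use t in {0, 1} with 1 = target weed; ``coords`` holds the source
    (row, col) of every pixel so any row can be traced back to the raster.
    """

    features: np.ndarray  # (N, n)
    labels: np.ndarray  # (N,) in {0, 1}
    coords: np.ndarray  # (N, 2) int

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        coords = np.asarray(self.coords, dtype=int)
        if features.ndim != 2:
            raise ValueError("features must be an (N, n) matrix")
        if labels.shape != (features.shape[0],):
            raise ValueError("labels length must equal the number of feature rows")
        if coords.shape != (features.shape[0], 2):
            raise ValueError("coords must be (N, 2)")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels.astype(np.int8))
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(count of t=1 target, count of t=0 other)."""
        pos = int(self.labels.sum())
        return pos, len(self) - pos

    def subset(self, idx: np.ndarray) -> "PixelDataset":
        return PixelDataset(self.features[idx], self.labels[idx], self.coords[idx])

    def to_frame(self, feature_names=FEATURE_NAMES) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(feature_names[: self.n_features]))
        df.insert(0, "col", self.coords[:, 1])
        df.insert(0, "row", self.coords[:, 0])
        df["label"] = self.labels
        return df


def sample_pixels(stack: FeatureStack, polygons: PolygonSet) -> PixelDataset:
    """One dataset row per polygon-covered cell, labeled by the polygon class.

    Class codes map to targets as 1 (weed) -> t=1 and 2 (other) -> t=0.
    """
    h, w = stack.shape
    rows, cols, labels = [], [], []
    seen: set[tuple[int, int]] = set()
    for rect in polygons.polygons:
        if rect.row0 < 0 or rect.col0 < 0 or rect.row1 > h or rect.col1 > w:
            raise SceneSizingError(f"polygon {rect} extends outside the {h}x{w} grid")
        rr, cc = rect.cells()
        for r, c in zip(rr.tolist(), cc.tolist()):
            if (r, c) in seen:
                continue
            seen.add((r, c))
            rows.append(r)
            cols.append(c)
            labels.append(1 if rect.class_code == TARGET else 0)
    coords = np.array([rows, cols], dtype=int).T.reshape(-1, 2)
    features = stack.layers[:, coords[:, 0], coords[:, 1]].T
    return PixelDataset(features=features, labels=np.array(labels), coords=coords)


def balance_calibration(dataset: PixelDataset, seed: int = 0) -> PixelDataset:
    """Equalize class counts by seeded undersampling of the majority class.

    The majority class is sampled without replacement down to the minority
    count; the balanced pool is then shuffled deterministically. Output size
    is 2 * min(class counts).
    """
    pos_idx = np.flatnonzero(dataset.labels == 1)
    neg_idx = np.flatnonzero(dataset.labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise DatasetCompositionError("both classes must be present to balance")
    rng = np.random.default_rng([seed, _STREAM_BALANCE])
    m = min(len(pos_idx), len(neg_idx))
    if len(pos_idx) > m:
        pos_idx = rng.choice(pos_idx, size=m, replace=False)
    if len(neg_idx) > m:
        neg_idx = rng.choice(neg_idx, size=m, replace=False)
    keep = np.concatenate([np.sort(pos_idx), np.sort(neg_idx)])
    keep = keep[rng.permutation(len(keep))]
    return dataset.subset(keep)


def split_train_validation(
    dataset: PixelDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[PixelDataset, PixelDataset]:
    """Seeded random partition; train size = ceil(train_fraction * N).

    The ceiling convention makes a 70% split of 2868 pixels come out as
    2008 training and 860 validation pixels.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = math.ceil(train_fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    rng = np.random.default_rng([seed, _STREAM_SPLIT])
    order = rng.permutation(n)
    return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location/scale estimated on training data and then frozen."""

    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        location = np.asarray(self.location, dtype=float)
        scale = np.asarray(self.scale, dtype=float)
        if location.shape != scale.shape or location.ndim != 1:
            raise ValueError("location and scale must be equal-length vectors")
        if (scale <= 0).any():
            raise ValueError("scales must be positive")
        object.__setattr__(self, "location", location)
        object.__setattr__(self, "scale", scale)


def fit_standardization(train: PixelDataset) -> StandardizationParams:
    """Mean/std per feature from the training set; zero-variance scales floored."""
    if len(train) == 0:
        raise ValueError("training set is empty")
    location = train.features.mean(axis=0)
    scale = train.features.std(axis=0)
    degenerate = scale < _SCALE_FLOOR
    if degenerate.any():
        names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i) for i in np.flatnonzero(degenerate)]
        logger.warning("zero-variance feature(s) %s: scale floored at %g", names, _SCALE_FLOOR)
        scale = np.where(degenerate, _SCALE_FLOOR, scale)
    return StandardizationParams(location=location, scale=scale)


def apply_standardization(params: StandardizationParams, data):
    """Standardize a PixelDataset, a FeatureStack, or a raw (N, n) matrix."""
    if isinstance(data, PixelDataset):
        z = (data.features - params.location) / params.scale
        return PixelDataset(features=z, labels=data.labels, coords=data.coords)
    if isinstance(data, FeatureStack):
        z = (data.layers - params.location[:, None, None]) / params.scale[:, None, None]
        return FeatureStack(layers=z, mask=data.mask)
    arr = np.asarray(data, dtype=float)
    return (arr - params.location) / params.scale


def block_mean_resample(band: np.ndarray, factor: int) -> np.ndarray:
    """Coarsen a grid by averaging factor x factor blocks (e.g. 0.1 m -> 0.5 m).

    Trailing rows/columns that do not fill a whole block are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    band = np.asarray(band, dtype=float)
    h, w = band.shape
    h2, w2 = h // factor, w // factor
    if h2 == 0 or w2 == 0:
        raise SceneSizingError("grid smaller than one block")
    trimmed = band[: h2 * factor, : w2 * factor]
    return trimmed.reshape(h2, factor, w2, factor).mean(axis=(1, 3))
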