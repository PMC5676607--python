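"""Whole-scene deployment and the end-to-end pipeline.

``classify_scene`` applies a trained model to every valid pixel of a feature
stack and returns a class raster (1 = target weed, 2 = other vegetation,
0 = no data). ``run_pipeline`` chains simulate -> features -> balance/split ->
fit -> evaluate -> map under one master seed and writes the artifact bundle:
model file, confusion table, relevance report, Hinton table, classification
rasters, and a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as sio
from .ard import FitResult, TrainConfig, fit, save_model
from .evaluation import confusion_matrix, hinton_export, overall_accuracy, predict_labels, relevance_report
from .features import (
    FEATURE_NAMES,
    FeatureStack,
    StandardizationParams,
    apply_standardization,
    balance_calibration,
    build_feature_stack,
    fit_standardization,
    sample_pixels,
    split_train_validation,
)
from .synthetic import ClassMap, SceneParams, generate_class_map, generate_polygons, generate_scene

__all__ = ["ClassificationMap", "RunConfig", "classify_scene", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)

NODATA = 0


@dataclass(frozen=True)
class ClassificationMap:
    """Per-pixel class raster with the green/yellow legend of the output maps."""

    labels: np.ndarray  # int16; 1 = target, 2 = other, 0 = no data
    legend: dict = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int16)
        if labels.ndim != 2 or not np.isin(labels, (0, 1, 2)).all():
            raise ValueError("classification map must be 2-D with codes {0, 1, 2}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(
            self,
            "legend",
            self.legend or {1: "S. marianum (green)", 2: "other vegetation (yellow)", 0: "no data"},
        )

    def classified_count(self) -> int:
        return int(np.sum(self.labels != NODATA))

    def agreement(self, truth: ClassMap) -> float:
        """Fraction of valid pixels whose class matches the ground truth."""
        valid = self.labels != NODATA
        if not valid.any():
            raise ValueError("no classified pixels")
        return float(np.mean(self.labels[valid] == truth.labels[valid]))


def classify_scene(
    model,
    stack: FeatureStack,
    standardization: StandardizationParams | None,
    threshold: float = 0.5,
    feature_indices: np.ndarray | None = None,
) -> ClassificationMap:
    """Classify every valid pixel of the stack with the trained model.

    ``standardization`` must be the parameters frozen on the training set.
    ``feature_indices`` selects stack layers when the model was trained on a
    feature subset.
    """
    X = stack.pixel_matrix()
    if feature_indices is not None:
        X = X[:, feature_indices]
    if X.shape[1] != model.n:
        raise ValueError(f"model expects {model.n} features, stack provides {X.shape[1]}")
    valid = stack.mask.ravel()
    labels = np.full(valid.shape, NODATA, dtype=np.int16)
    Xv = X[valid]
    if standardization is not None:
        Xv = apply_standardization(standardization, Xv)
    pred = predict_labels(model, Xv, threshold)
    labels[valid] = np.where(pred == 1, 1, 2)
    return ClassificationMap(labels=labels.reshape(stack.shape))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class SceneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    height: int = 240
    width: int = 240
    patch_scale: float = 25.0
    coverage_fraction: float = Field(0.45, gt=0.0, lt=1.0)
    mean_target: dict[str, float] = {"green": 0.12, "red": 0.10, "nir": 0.50}
    mean_other: dict[str, float] = {"green": 0.12, "red": 0.10, "nir": 0.35}
    noise_sd: dict[str, float] = {"green": 0.002, "red": 0.002, "nir": 0.03}
    pixel_noise_sd: dict[str, float] = {"green": 0.015, "red": 0.015, "nir": 0.035}
    texture_contrast: float = 0.06
    noise_scale: float = 4.0


class PolygonConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_target: int = 17
    n_other: int = 13
    rect_height: int = 11
    rect_width: int = 11


class FeatureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_size: int = 7
    standardize: bool = True
    use_features: list[str] = list(FEATURE_NAMES)

    @model_validator(mode="after")
    def _check_features(self):
        unknown = set(self.use_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if not self.use_features:
            raise ValueError("use_features must not be empty")
        return self


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden_count: int = 8
    inner_iters: int = 200
    outer_cycles: int = 20
    alpha_tol: float = 1e-3
    alpha_init: float = 0.01
    alpha_max: float = 1e6
    alpha_min: float = 0.1
    train_fraction: float = Field(0.7, gt=0.0, lt=1.0)


class EvalSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float = 0.5


class RunConfig(BaseModel):
    """Schema-validated configuration of a full pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    scene: SceneConfig = SceneConfig()
    polygons: PolygonConfig = PolygonConfig()
    features: FeatureConfig = FeatureConfig()
    train: TrainSection = TrainSection()
    evaluation: EvalSection = EvalSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineResult:
    config: RunConfig
    class_map: ClassMap
    fit_result: FitResult
    standardization: StandardizationParams | None
    confusion: "object"
    validation_accuracy: float
    classification_map: ClassificationMap
    map_agreement: float
    manifest: dict


def _stage(name: str):
    """Context helper: logs per-stage timing and re-raises with stage context."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute simulate -> features -> balance/split -> fit -> evaluate -> map.

    When ``outdir`` is given, writes the artifact bundle there (model JSON,
    confusion CSV + text, relevance and Hinton reports, class rasters, PNG
    quicklook, and ``manifest.json``). Fully deterministic for a fixed config.
    """
    seed = config.seed
    sc = config.scene
    with _stage("simulate"):
        class_map = generate_class_map(sc.height, sc.width, sc.patch_scale, sc.coverage_fraction, seed)
        params = SceneParams(
            mean_target=dict(sc.mean_target),
            mean_other=dict(sc.mean_other),
            noise_sd=dict(sc.noise_sd),
            pixel_noise_sd=dict(sc.pixel_noise_sd),
            texture_contrast=sc.texture_contrast,
            noise_scale=sc.noise_scale,
            seed=seed,
        )
        scene = generate_scene(class_map, params)
        polygons = generate_polygons(
            class_map,
            (config.polygons.n_target, config.polygons.n_other),
            (config.polygons.rect_height, config.polygons.rect_width),
            seed,
        )

    with _stage("features"):
        stack = build_feature_stack(scene, config.features.window_size)
        feature_idx = np.array([FEATURE_NAMES.index(f) for f in config.features.use_features])
        dataset = sample_pixels(stack, polygons)
        if len(feature_idx) != len(FEATURE_NAMES):
            dataset = type(dataset)(
                features=dataset.features[:, feature_idx],
                labels=dataset.labels,
                coords=dataset.coords,
            )
        n_target, n_other = dataset.class_counts()

    with _stage("balance-split"):
        balanced = balance_calibration(dataset, seed)
        train_set, valid_set = split_train_validation(balanced, config.train.train_fraction, seed)

    with _stage("standardize"):
        standardization = None
        if config.features.standardize:
            standardization = fit_standardization(train_set)
            train_z = apply_standardization(standardization, train_set)
            valid_z = apply_standardization(standardization, valid_set)
        else:
            train_z, valid_z = train_set, valid_set

    with _stage("fit"):
        tc = TrainConfig(
            hidden_count=config.train.hidden_count,
            inner_iters=config.train.inner_iters,
            outer_cycles=config.train.outer_cycles,
            alpha_tol=config.train.alpha_tol,
            alpha_init=config.train.alpha_init,
            alpha_max=config.train.alpha_max,
            alpha_min=config.train.alpha_min,
            seed=seed,
        )
        result = fit(train_z, tc)

    with _stage("evaluate"):
        pred = predict_labels(result.model, valid_z.features, config.evaluation.threshold)
        confusion = confusion_matrix(valid_z.labels, pred)
        accuracy = overall_accuracy(confusion)
        feature_names = tuple(config.features.use_features)
        relevance = relevance_report(result.model, result.hyperparameters, feature_names)
        hinton = hinton_export(result.model, feature_names)

    with _stage("map"):
        cmap = classify_scene(
            result.model,
            stack,
            standardization,
            config.evaluation.threshold,
            feature_idx if len(feature_idx) != len(FEATURE_NAMES) else None,
        )
        agreement = cmap.agreement(class_map)

    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_features": len(feature_idx),
        "n_weight_groups": len(result.groups),
        "counts": {
            "target_pixels": n_target,
            "other_pixels": n_other,
            "calibration": len(balanced),
            "train": len(train_set),
            "validation": len(valid_set),
            "scene_pixels": int(np.prod(stack.shape)),
        },
        "validation_accuracy_percent": accuracy,
        "validation_accuracy_fraction": confusion.accuracy_fraction(),
        "map_agreement_percent": round(100.0 * agreement, 2),
        "map_agreement_fraction": agreement,
        "confusion_counts": confusion.counts.tolist(),
        "alphas": {
            name: float(result.hyperparameters.alphas[k])
            for k, name in enumerate(config.features.use_features)
        },
        "converged": result.converged,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with _stage("write"):
            save_model(outdir / "model.json", result.model, result.hyperparameters, standardization, tc)
            confusion.to_frame().to_csv(outdir / "confusion.csv")
            (outdir / "confusion.txt").write_text(confusion.to_text() + "\n")
            relevance.table.to_csv(outdir / "relevance.csv")
            (outdir / "relevance.txt").write_text(relevance.to_text() + "\n")
            hinton.to_frame().to_csv(outdir / "hinton.csv")
            (outdir / "hinton.txt").write_text(hinton.to_text() + "\n")
            sio.write_class_map_tiff(outdir / "ground_truth.tif", class_map)
            sio.write_label_raster(outdir / "classification.tif", cmap.labels)
            sio.write_map_png(outdir / "classification.png", cmap.labels)
            sio.write_scene_npz(outdir / "scene.npz", scene, class_map)
            sio.write_polygons_geojson(outdir / "polygons.geojson", polygons)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        config=config,
        class_map=class_map,
        fit_result=result,
        standardization=standardization,
        confusion=confusion,
        validation_accuracy=accuracy,
        classification_map=cmap,
        map_agreement=agreement,
        manifest=manifest,
    )
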