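import warnings

import numpy as np
import pytest

from silymap.pipeline import RunConfig, run_pipeline
from silymap.synthetic import SceneParams, generate_class_map, generate_polygons, generate_scene
from silymap.features import build_feature_stack, sample_pixels


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study conditions (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_pipeline(RunConfig(seed=0))


@pytest.fixture(scope="session")
def small_scene_bundle():
    """A small scene with stack and polygons for fast structural tests."""
    class_map = generate_class_map(96, 96, 10, 0.4, seed=3)
    scene = generate_scene(class_map, SceneParams(seed=3))
    stack = build_feature_stack(scene)
    polygons = generate_polygons(class_map, (6, 5), (6, 6), seed=3)
    dataset = sample_pixels(stack, polygons)
    return class_map, scene, stack, polygons, dataset


def window_variance_oracle(band: np.ndarray, window: int = 7) -> np.ndarray:
    """Loop-based population variance of each reflect-padded window."""
    half = window // 2
    padded = np.pad(band, half, mode="symmetric")
    out = np.empty_like(band, dtype=float)
    for i in range(band.shape[0]):
        for j in range(band.shape[1]):
            block = padded[i : i + window, j : j + window]
            out[i, j] = block.var()
    return out
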