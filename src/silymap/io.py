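"""File formats: multiband rasters, sampling polygons, pixel datasets.

Rasters are written as plain multiband TIFF (via tifffile) and/or as a
portable ``.npz`` grid archive; polygons as GeoJSON (pixel coordinates, a
``class`` property per feature) and as a rectangle-bounds CSV; pixel datasets
as CSV with columns row,col,green,red,nir,texture,label.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .features import FEATURE_NAMES, PixelDataset
from .synthetic import BAND_NAMES, ClassMap, PolygonSet, Rectangle, SpectralScene

__all__ = [
    "write_scene_tiff",
    "read_scene_tiff",
    "write_scene_npz",
    "read_scene_npz",
    "write_class_map_tiff",
    "read_class_map_tiff",
    "write_polygons_geojson",
    "read_polygons_geojson",
    "write_polygons_csv",
    "read_polygons_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_label_raster",
    "write_map_png",
    "MAP_COLORS",
]

# classification map color table: green = target weed, yellow = other, black = no data
MAP_COLORS = {1: (34, 139, 34), 2: (255, 221, 51), 0: (0, 0, 0)}


def write_scene_tiff(path: str | Path, scene: SpectralScene) -> None:
    """3-band TIFF in band order green, red, NIR (float64, band-sequential)."""
    data = np.stack([scene.green, scene.red, scene.nir])
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate",
        metadata={"bands": list(BAND_NAMES)},
    )


def read_scene_tiff(path: str | Path) -> SpectralScene:
    data = tifffile.imread(path)
    if data.ndim != 3 or data.shape[0] != 3:
        raise ValueError("expected a 3-band raster (bands first)")
    return SpectralScene(green=data[0], red=data[1], nir=data[2])


def write_scene_npz(path: str | Path, scene: SpectralScene, class_map: ClassMap | None = None) -> None:
    """Portable grid archive; optionally bundles the ground-truth class map."""
    arrays = {"green": scene.green, "red": scene.red, "nir": scene.nir, "mask": scene.mask}
    if class_map is not None:
        arrays["class_map"] = class_map.labels
    np.savez(path, **arrays)


def read_scene_npz(path: str | Path) -> tuple[SpectralScene, ClassMap | None]:
    with np.load(path) as z:
        scene = SpectralScene(green=z["green"], red=z["red"], nir=z["nir"], mask=z["mask"])
        class_map = ClassMap(labels=z["class_map"]) if "class_map" in z else None
    return scene, class_map


def write_class_map_tiff(path: str | Path, class_map: ClassMap) -> None:
    tifffile.imwrite(path, class_map.labels.astype(np.int16))


def read_class_map_tiff(path: str | Path) -> ClassMap:
    return ClassMap(labels=tifffile.imread(path))


def write_polygons_geojson(path: str | Path, polygons: PolygonSet) -> None:
    """GeoJSON FeatureCollection in pixel coordinates (x = col, y = row)."""
    features = []
    for rect in polygons.polygons:
        ring = [
            [rect.col0, rect.row0],
            [rect.col1, rect.row0],
            [rect.col1, rect.row1],
            [rect.col0, rect.row1],
            [rect.col0, rect.row0],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"class": rect.class_code},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_polygons_geojson(path: str | Path) -> PolygonSet:
    data = json.loads(Path(path).read_text())
    rects = []
    for feat in data["features"]:
        ring = feat["geometry"]["coordinates"][0]
        cols = [p[0] for p in ring]
        rows = [p[1] for p in ring]
        rects.append(
            Rectangle(
                row0=int(min(rows)),
                col0=int(min(cols)),
                row1=int(max(rows)),
                col1=int(max(cols)),
                class_code=int(feat["properties"]["class"]),
            )
        )
    return PolygonSet(polygons=tuple(rects))


def write_polygons_csv(path: str | Path, polygons: PolygonSet) -> None:
    df = pd.DataFrame(
        [(r.row0, r.col0, r.row1, r.col1, r.class_code) for r in polygons.polygons],
        columns=["row0", "col0", "row1", "col1", "class"],
    )
    df.to_csv(path, index=False)


def read_polygons_csv(path: str | Path) -> PolygonSet:
    df = pd.read_csv(path)
    rects = tuple(
        Rectangle(int(r.row0), int(r.col0), int(r.row1), int(r.col1), int(r["class"]))
        for _, r in df.iterrows()
    )
    return PolygonSet(polygons=rects)


def write_dataset_csv(path: str | Path, dataset: PixelDataset) -> None:
    # %.17g round-trips float64 exactly
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dataset_csv(path: str | Path) -> PixelDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    feature_cols = [c for c in FEATURE_NAMES if c in df.columns]
    return PixelDataset(
        features=df[feature_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(),
        coords=df[["row", "col"]].to_numpy(dtype=int),
    )


def write_label_raster(path: str | Path, labels: np.ndarray) -> None:
    """Single-band int16 raster of class codes (0 = no data)."""
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int16))


def write_map_png(path: str | Path, labels: np.ndarray) -> None:
    """Color-coded quicklook: green = target weed, yellow = other vegetation."""
    labels = np.asarray(labels)
    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for code, color in MAP_COLORS.items():
        rgb[labels == code] = color
    Image.fromarray(rgb).save(path)
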