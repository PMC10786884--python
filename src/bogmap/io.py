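"""Raster, vector and table I/O.

Rasters are multi-band TIFFs (band-interleaved, float32 or int16) written
with ``tifffile``; grid metadata (band names, pixel size, nodata convention)
travels in a JSON document stored in the TIFF description tag.  Polygons are
GeoJSON FeatureCollections with a ``class_code`` property; tables are plain
CSV.  All three round-trip exactly: ``read(write(x)) == x``.

Coordinate convention (used everywhere in the package): row-major grids,
origin at the top-left, polygon coordinates in pixel units with x = column,
y = row, pixel (r, c) centred at (c + 0.5, r + 0.5).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

from .lucip import BAND_NAMES
from .synthetic import ClassMap, Scene, TrainingPolygons


class FormatError(ValueError):
    """Raised when a file does not match the expected layout."""


def write_raster(
    path: str | Path,
    data: np.ndarray,
    band_names: list[str] | None = None,
    pixel_size_ha: float | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write a (bands, H, W) or (H, W) array as a described multi-band TIFF."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    meta = {
        "band_names": band_names or [f"band_{i}" for i in range(data.shape[0])],
        "pixel_size_ha": pixel_size_ha,
        "nodata": "nan" if np.issubdtype(data.dtype, np.floating) else 0,
    }
    if extra_meta:
        meta.update(extra_meta)
    if len(meta["band_names"]) != data.shape[0]:
        raise FormatError(f"{path}: band_names length != band count")
    tifffile.imwrite(
        str(path), data, photometric="minisblack", description=json.dumps(meta)
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a raster written by :func:`write_raster`; returns (data, meta)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected raster file missing: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if data.ndim == 2:
        data = data[None]
    return data, meta


def write_scene(path: str | Path, scene: Scene) -> None:
    """One scene -> 11-band TIFF: the 10 reflectance bands then the QA band."""
    stack = np.concatenate(
        [scene.bands, scene.qa[None].astype(np.float32)], axis=0
    )
    write_raster(
        path,
        stack,
        band_names=BAND_NAMES + ["QA"],
        extra_meta={
            "date": scene.date.isoformat(),
            "cloud_fraction": scene.cloud_fraction,
        },
    )


def read_scene(path: str | Path) -> Scene:
    data, meta = read_raster(path)
    if data.shape[0] != len(BAND_NAMES) + 1:
        raise FormatError(f"{path}: expected {len(BAND_NAMES) + 1} bands")
    return Scene(
        bands=data[:-1].astype(np.float32),
        qa=data[-1].astype(np.uint16),
        date=datetime.date.fromisoformat(meta["date"]),
        cloud_fraction=float(meta["cloud_fraction"]),
    )


def write_scene_series(outdir: str | Path, scenes: list[Scene]) -> pd.DataFrame:
    """Write scenes plus an index CSV (filename, date, cloud_fraction)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, scene in enumerate(scenes):
        fname = f"scene_{i:03d}.tif"
        write_scene(outdir / fname, scene)
        rows.append(
            {"filename": fname, "date": scene.date.isoformat(),
             "cloud_fraction": scene.cloud_fraction}
        )
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "scene_index.csv", index=False)
    return index


def read_scene_series(indir: str | Path) -> list[Scene]:
    indir = Path(indir)
    index_path = indir / "scene_index.csv"
    if not index_path.exists():
        raise FileNotFoundError(f"expected scene index missing: {index_path}")
    index = pd.read_csv(index_path)
    return [read_scene(indir / fname) for fname in index["filename"]]


def write_class_map(path: str | Path, cmap: ClassMap) -> None:
    write_raster(
        path,
        cmap.grid.astype(np.int16),
        band_names=["class_code"],
        pixel_size_ha=cmap.pixel_size_ha,
    )


def read_class_map(path: str | Path) -> ClassMap:
    data, meta = read_raster(path)
    return ClassMap(
        data[0].astype(np.int16), pixel_size_ha=float(meta["pixel_size_ha"])
    )


def write_polygons(path: str | Path, polygons: TrainingPolygons) -> None:
    """GeoJSON FeatureCollection; class code in the ``class_code`` property."""
    features = [
        {
            "type": "Feature",
            "geometry": shapely_mapping(poly),
            "properties": {"class_code": int(code)},
        }
        for poly, code in polygons.items
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_polygons(path: str | Path) -> TrainingPolygons:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected polygon file missing: {path}")
    try:
        obj = json.loads(path.read_text())
        items = [
            (shapely_shape(f["geometry"]), int(f["properties"]["class_code"]))
            for f in obj["features"]
        ]
    except (KeyError, json.JSONDecodeError) as e:
        raise FormatError(f"{path}: malformed GeoJSON ({e})") from e
    return TrainingPolygons(items)


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected table missing: {path}")
    return pd.read_csv(path, index_col=index_col)
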