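"""Minimal raster / vector I/O on plain text-friendly formats.

Rasters are multi-band float32 TIFFs (``tifffile``) with a JSON document in
the TIFF ImageDescription carrying grid metadata (pixel size in meters, band
names, nodata value, free-form tags).  Polygons travel as GeoJSON in grid
coordinates (meters, x = east/col, y = south/row).  NaN is the in-memory
nodata representation throughout; the sentinel value is used on disk only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

NODATA = -9999.0


def write_raster(
    path: str | Path,
    data: np.ndarray,
    band_names: Sequence[str] | None = None,
    pixel_size: float = 20.0,
    nodata: float = NODATA,
    tags: dict | None = None,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) float raster.

    NaN cells are stored as ``nodata``; integer arrays are stored untouched.
    """
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError("raster data must be 2-D or 3-D (bands, rows, cols)")
    meta = {
        "pixel_size": float(pixel_size),
        "nodata": float(nodata),
        "band_names": list(band_names) if band_names is not None else None,
        "tags": tags or {},
    }
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float32).copy()
        out[~np.isfinite(out)] = np.float32(nodata)
    else:
        out = arr
    kwargs = {"photometric": "minisblack"}
    if out.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(str(path), out, description=json.dumps(meta), **kwargs)


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a raster written by :func:`write_raster`.

    Returns ``(data, meta)`` where float nodata cells are NaN and ``data``
    always has a leading band axis.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    meta.setdefault("pixel_size", 20.0)
    meta.setdefault("nodata", NODATA)
    meta.setdefault("band_names", None)
    meta.setdefault("tags", {})
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
        arr[arr == meta["nodata"]] = np.nan
    return arr, meta


def write_geojson(path: str | Path, geoms: Sequence[BaseGeometry]) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"id": i}, "geometry": mapping(g)}
            for i, g in enumerate(geoms)
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_geojson(path: str | Path) -> list[BaseGeometry]:
    doc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in doc["features"]]


def rasterize_polygons(
    geoms: Sequence[BaseGeometry], shape_rc: tuple[int, int], pixel_size: float = 20.0
) -> np.ndarray:
    """Boolean mask of pixels whose center falls inside any polygon."""
    rows, cols = shape_rc
    if not geoms:
        raise ValueError("empty polygon set")
    union = shapely.union_all(list(geoms))
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    x = (cc.ravel() + 0.5) * pixel_size
    y = (rr.ravel() + 0.5) * pixel_size
    inside = shapely.contains_xy(union, x, y)
    return inside.reshape(rows, cols)


def sha256_file(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
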