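"""Spectral vegetation indices and the 0-1 rescaling used before binning.

Three trait proxies are mapped from Sentinel-2-style surface reflectance:

* CHL — canopy chlorophyll, via the red-edge chlorophyll index
  ``CIre = rho783 / rho704 - 1`` (bands B7, B5);
* CCR — carotenoid/chlorophyll ratio, via
  ``CCI = (rho560 - rho664) / (rho560 + rho664)`` (bands B3, B4);
* EWT — equivalent water thickness, via
  ``NDII = (rho865 - rho1614) / (rho865 + rho1614)`` (bands B8A, B11).

Canopy water status for drought response uses
``NDWI = (rho833 - rho1614) / (rho833 + rho1614)`` (bands B8, B11), and the
masking chain uses ``NDVI`` from bands B4 and B8A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel-2 band center wavelengths (nm) for the 10/20 m bands used here.
BAND_WAVELENGTHS_NM = {
    "B2": 492, "B3": 560, "B4": 664, "B5": 704, "B6": 740,
    "B7": 783, "B8": 833, "B8A": 865, "B11": 1614, "B12": 2202,
}

BAND_ORDER = tuple(BAND_WAVELENGTHS_NM)

#: index -> (numerator band, denominator/reference band)
INDEX_BANDS = {
    "CIre": ("B7", "B5"),
    "CCI": ("B3", "B4"),
    "NDII": ("B8A", "B11"),
    "NDWI": ("B8", "B11"),
    "NDVI": ("B8A", "B4"),
}

#: trait role of each diversity index
TRAIT_OF_INDEX = {"CIre": "CHL", "CCI": "CCR", "NDII": "EWT"}

_DENOM_EPS = 1e-9


@dataclass
class ReflectanceScene:
    """One acquisition's band stack on a common grid, reflectance in [0, 1]."""

    bands: dict[str, np.ndarray]
    pixel_size: float = 20.0
    date_tag: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError("all bands must share one grid")

    def stack(self, order=BAND_ORDER) -> np.ndarray:
        return np.stack([self.bands[b] for b in order])

    @classmethod
    def from_stack(cls, arr: np.ndarray, pixel_size: float = 20.0,
                   date_tag: str = "", order=BAND_ORDER) -> "ReflectanceScene":
        return cls({b: arr[i] for i, b in enumerate(order)}, pixel_size, date_tag)


@dataclass
class IndexRaster:
    values: np.ndarray
    index_name: str
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.values)

    def masked(self) -> np.ndarray:
        """Values with invalid cells as NaN."""
        out = np.array(self.values, dtype=float)
        out[~self.valid] = np.nan
        return out


def compute_index(scene: ReflectanceScene, index_name: str) -> IndexRaster:
    """Per-pixel spectral index; invalid where inputs are nodata or the
    denominator magnitude is below 1e-9."""
    if index_name not in INDEX_BANDS:
        raise KeyError(f"unknown index {index_name!r}")
    a_name, b_name = INDEX_BANDS[index_name]
    for name in (a_name, b_name):
        if name not in scene.bands:
            raise KeyError(f"scene lacks band {name} required by {index_name}")
    a = np.asarray(scene.bands[a_name], dtype=float)
    b = np.asarray(scene.bands[b_name], dtype=float)
    if index_name == "CIre":
        denom = b
    else:
        denom = a + b
    valid = np.isfinite(a) & np.isfinite(b) & (np.abs(denom) >= _DENOM_EPS)
    vals = np.full(a.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        if index_name == "CIre":
            np.divide(a, b, out=vals, where=valid)
            vals = np.where(valid, vals - 1.0, np.nan)
        else:
            np.divide(a - b, denom, out=vals, where=valid)
    vals[~valid] = np.nan
    return IndexRaster(vals, index_name, valid)


def rescale01(raster: IndexRaster, clip_pct: float = 0.1) -> IndexRaster:
    """Rescale an index map to [0, 1] with symmetric tail clipping.

    Values at/below the ``clip_pct`` percentile map to 0, at/above the
    ``100 - clip_pct`` percentile map to 1, linear in between (linearly
    interpolated empirical percentiles).  A constant raster maps to 0.5.
    """
    vals = raster.masked()
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("rescale01 on an all-invalid raster")
    lo = float(np.percentile(finite, clip_pct))
    hi = float(np.percentile(finite, 100.0 - clip_pct))
    out = np.full(vals.shape, np.nan)
    if hi - lo < 1e-300:
        out[np.isfinite(vals)] = 0.5
    else:
        scaled = (vals - lo) / (hi - lo)
        out = np.clip(scaled, 0.0, 1.0)
    return IndexRaster(out, raster.index_name, np.isfinite(out))


def resample_mean(raster10m: np.ndarray, policy: str = "valid_mean") -> np.ndarray:
    """Aggregate a 10 m raster to 20 m by 2x2 block means.

    ``valid_mean`` averages the finite block members and is invalid only if
    all four are; ``strict`` propagates any NaN.
    """
    arr = np.asarray(raster10m, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a single-band 2-D raster")
    r, c = arr.shape
    if r % 2 or c % 2:
        raise ValueError("input dimensions must be even")
    blocks = arr.reshape(r // 2, 2, c // 2, 2).transpose(0, 2, 1, 3).reshape(r // 2, c // 2, 4)
    if policy == "strict":
        return blocks.mean(axis=-1)
    if policy == "valid_mean":
        finite = np.isfinite(blocks)
        total = np.where(finite, blocks, 0.0).sum(axis=-1)
        count = finite.sum(axis=-1)
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)
    raise ValueError(f"unknown nodata policy {policy!r}")
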