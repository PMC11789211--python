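"""Yearly NDWI composites and drought resistance / recovery / resilience.

Each year's canopy water status is the per-pixel median NDWI over that
year's August acquisitions.  Responses are fractional change ratios between
yearly composites (a value of -0.2 means a 20% NDWI decline):

* resistance  = (NDWI_2018 - NDWI_2017) / NDWI_2017  (change into the drought)
* recovery    = (NDWI_2019 - NDWI_2018) / NDWI_2018  (first post-drought year)
* resilience  = (NDWI_2020 - NDWI_2017) / NDWI_2017  (two-year net change)

Using the second post-drought year for resilience avoids a linear
combination of resistance and recovery.  Ratios are undefined where the
baseline magnitude falls below an epsilon guard (default 1e-3), since NDWI
near zero makes percent changes unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectral_indices import IndexRaster

DEFAULT_EPS = 1e-3


@dataclass
class YearlyNdwi:
    year_tag: str
    ndwi: np.ndarray  # NaN where invalid
    n_scenes: int


@dataclass
class DroughtResponseMap:
    resistance: np.ndarray
    recovery: np.ndarray
    resilience: np.ndarray
    eps: float = DEFAULT_EPS

    @property
    def valid(self) -> np.ndarray:
        return (
            np.isfinite(self.resistance)
            & np.isfinite(self.recovery)
            & np.isfinite(self.resilience)
        )


def median_composite(index_rasters: Sequence[IndexRaster], year_tag: str = "") -> YearlyNdwi:
    """Per-pixel median over valid observations; invalid where none exist."""
    if not index_rasters:
        raise ValueError("no rasters to composite")
    shapes = {r.values.shape for r in index_rasters}
    if len(shapes) > 1:
        raise ValueError("grid mismatch in composite inputs")
    stack = np.stack([r.masked() for r in index_rasters])
    finite = np.isfinite(stack)
    any_valid = finite.any(axis=0)
    out = np.full(stack.shape[1:], np.nan)
    if np.any(any_valid):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(stack, axis=0)
        out[any_valid] = med[any_valid]
    return YearlyNdwi(year_tag, out, len(index_rasters))


def change_ratio(base: np.ndarray, target: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """(target - base) / base where |base| >= eps and both valid; else NaN."""
    b = np.asarray(base, dtype=float)
    t = np.asarray(target, dtype=float)
    if b.shape != t.shape:
        raise ValueError("grid mismatch")
    ok = np.isfinite(b) & np.isfinite(t) & (np.abs(b) >= eps)
    out = np.full(b.shape, np.nan)
    np.divide(t - b, b, out=out, where=ok)
    out[~ok] = np.nan
    return out


def drought_responses(
    y2017: YearlyNdwi,
    y2018: YearlyNdwi,
    y2019: YearlyNdwi,
    y2020: YearlyNdwi,
    eps: float = DEFAULT_EPS,
) -> DroughtResponseMap:
    years = (y2017, y2018, y2019, y2020)
    shapes = {y.ndwi.shape for y in years}
    if len(shapes) > 1:
        raise ValueError("yearly composites on different grids")
    return DroughtResponseMap(
        resistance=change_ratio(y2017.ndwi, y2018.ndwi, eps),
        recovery=change_ratio(y2018.ndwi, y2019.ndwi, eps),
        resilience=change_ratio(y2017.ndwi, y2020.ndwi, eps),
        eps=eps,
    )
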