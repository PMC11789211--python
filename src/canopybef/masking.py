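"""Forest-mask construction from multi-date scenes.

The chain mirrors a standard optical pre-processing recipe: a simple
reflectance-threshold cloud/shadow flag (B2 < 5% and B8A > 15%), clipping to
forest polygons, an NDVI lower threshold to drop gaps/dead canopies, a dark-
pixel shadow screen on B6 and B12, and a 2-of-3 multi-date vote.  Robust
thresholds are median +/- c * MAD ("median outliers"); all comparisons are
strict inequalities so boundary behavior is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.measure import label
from skimage.morphology import disk, erosion

from .gridio import rasterize_polygons
from .spectral_indices import ReflectanceScene, compute_index

CLOUD_B2_MAX = 0.05
CLOUD_B8A_MIN = 0.15


@dataclass
class PixelMask:
    """Boolean validity raster plus the ordered rule names that produced it."""

    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    @property
    def count_valid(self) -> int:
        return int(np.count_nonzero(self.values))

    def area_km2(self, pixel_size: float = 20.0) -> float:
        return self.count_valid * pixel_size**2 / 1e6


def area_km2(n_pixels: int, pixel_size: float = 20.0) -> float:
    """Ground area of ``n_pixels`` square pixels, in km^2."""
    return n_pixels * pixel_size**2 / 1e6


def cloudfree_mask(scene: ReflectanceScene) -> PixelMask:
    """True where B2 < 0.05 and B8A > 0.15 (cloud- and cloud-shadow-free)."""
    for b in ("B2", "B8A"):
        if b not in scene.bands:
            raise KeyError(f"scene lacks band {b}")
    b2 = scene.bands["B2"]
    b8a = scene.bands["B8A"]
    ok = (b2 < CLOUD_B2_MAX) & (b8a > CLOUD_B8A_MIN)
    ok &= np.isfinite(b2) & np.isfinite(b8a)
    return PixelMask(ok, ["cloudfree(B2<0.05 & B8A>0.15)"])


def median_outlier_threshold(values: np.ndarray, side: str, c: float = 3.0) -> float:
    """Robust outlier threshold: median -/+ c * MAD (median absolute deviation)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    if side == "lower":
        return med - c * mad
    if side == "upper":
        return med + c * mad
    raise ValueError("side must be 'lower' or 'upper'")


def _scene_valid(
    scene: ReflectanceScene, poly_mask: np.ndarray, c_ndvi: float, c_shadow: float
) -> tuple[np.ndarray, dict]:
    cf = cloudfree_mask(scene).values
    ndvi = compute_index(scene, "NDVI").masked()
    sample = ndvi[poly_mask & np.isfinite(ndvi)]
    thresholds = {}
    valid = cf & poly_mask
    # outlier screens EXCLUDE pixels strictly below the threshold, so a
    # zero-dispersion sample (MAD = 0, threshold = median) excludes nothing
    if sample.size:
        t_ndvi = median_outlier_threshold(sample, "lower", c_ndvi)
        thresholds["ndvi"] = t_ndvi
        valid &= ~(ndvi < t_ndvi) & np.isfinite(ndvi)
    for band in ("B6", "B12"):
        vals = np.asarray(scene.bands[band], dtype=float)
        bsample = vals[poly_mask & np.isfinite(vals)]
        if bsample.size:
            t = median_outlier_threshold(bsample, "lower", c_shadow)
            thresholds[f"shadow_{band}"] = t
            valid &= ~(vals < t) & np.isfinite(vals)
    return valid, thresholds


def build_forest_mask(
    scenes: Sequence[ReflectanceScene],
    polygons,
    c_ndvi: float = 3.0,
    c_shadow: float = 3.0,
    min_votes: int = 2,
    pixel_size: float | None = None,
) -> PixelMask:
    """Combine per-scene validity into the final forest mask.

    A pixel is valid in one scene iff it is cloud-free, inside the forest
    polygons, not below the scene's lower NDVI median-outlier threshold
    (computed within the polygon area), and not flagged as shadow (B6 and
    B12 each not below their lower median-outlier thresholds).  The final mask
    keeps pixels valid in at least ``min_votes`` of the scenes (equivalent
    to a mean of the boolean layers >= min_votes / n).
    """
    if not scenes:
        raise ValueError("no scenes given")
    shapes = {s.shape for s in scenes}
    if len(shapes) > 1:
        raise ValueError("scene grid mismatch")
    ps = pixel_size if pixel_size is not None else scenes[0].pixel_size
    poly_mask = rasterize_polygons(polygons, scenes[0].shape, ps)
    votes = np.zeros(scenes[0].shape, dtype=int)
    provenance = [f"polygons({ps} m grid)"]
    all_thresholds = {}
    for i, sc in enumerate(scenes):
        valid, thr = _scene_valid(sc, poly_mask, c_ndvi, c_shadow)
        votes += valid
        all_thresholds[sc.date_tag or f"scene{i}"] = thr
    final = votes >= min_votes
    provenance += [
        f"cloudfree+ndvi(c={c_ndvi})+shadow(c={c_shadow}) per scene",
        f"vote>={min_votes}/{len(scenes)}",
    ]
    mask = PixelMask(final, provenance)
    mask.thresholds = all_thresholds  # type: ignore[attr-defined]
    return mask


def exclude_edge_patches(
    mask: PixelMask, min_patch_px: int = 28, erosion_px: int = 0
) -> PixelMask:
    """Drop small 8-connected patches, then erode; never adds pixels.

    Small, isolated forest patches carry edge-biased diversity values; the
    default minimum patch size is one kernel area (28 px at radius 3).
    """
    if min_patch_px < 0 or erosion_px < 0:
        raise ValueError("parameters must be non-negative")
    values = np.asarray(mask.values, dtype=bool)
    out = values.copy()
    if min_patch_px > 1:
        lab = label(values, connectivity=2)
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < min_patch_px)
        out[np.isin(lab, small[small > 0])] = False
    if erosion_px > 0:
        out = erosion(out, disk(erosion_px)).astype(bool)
    return PixelMask(
        out,
        list(mask.provenance)
        + [f"exclude_patches(<{min_patch_px}px)", f"erode({erosion_px}px)"],
    )
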