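"""Synthetic multi-date reflectance landscapes with known ground truth.

The generator emulates the structure of the study data — a 20 m pixel grid
over a patchy mixed-species forest, observed by a 10-band optical sensor on
three early-summer dates (for the diversity composite) and on several
August dates in each of four consecutive years (for the drought-response
composites) — while keeping every quantity the downstream pipeline
estimates available as ground truth.

Construction, in order:

1. species patches by seeded multi-source flood fill (per-species seed
   counts), giving spatially varying local species richness;
2. per-pixel trait triples (CHL, CCR, EWT) = species values + within-
   species Gaussian jitter;
3. truth functional diversity maps computed on the noiseless trait maps
   (rescaled 0-1, circular kernel, convex-hull richness), then themselves
   rescaled to [0, 1] — the units in which the regression stage estimates
   effects;
4. a diversity -> drought-response linkage: each pixel's year-2 NDWI dip is
   linear in rescaled local richness (slope ``beta_ric``) and quadratic in
   rescaled evenness (``gamma_eve``), plus per-subregion offsets; year 3
   rebounds and year 4 partially relapses (the qualitative dip/rebound/
   relapse trajectory of the 2018 drought);
5. scene rendering by *inverting* the index definitions: one band of each
   index pair is fixed at a configurable anchor reflectance and the other
   solved so the index equals the pixel's target, then Gaussian band noise
   and cloud/shadow contamination are added.

All randomness flows from one root seed through named substreams, so the
same (config, seed) is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box, mapping, shape

from . import gridio
from .functional_diversity import circular_kernel, map_functional_diversity
from .spectral_indices import BAND_ORDER, IndexRaster, ReflectanceScene, rescale01


class ConfigError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """A pixel target fell outside the invertible range of its index."""


# named substreams off the root seed (order is part of the format)
_STREAMS = {"species": 1, "patches": 2, "subregions": 3, "field": 4,
            "jitter": 5, "regions_fx": 6, "clearings": 7, "render": 100}


@dataclass
class LandscapeConfig:
    rows: int = 128
    cols: int = 128
    pixel_size: float = 20.0
    # community structure
    n_species: int = 8
    seeds_per_species: int = 6
    trait_jitter_sd: float = 0.03
    chl_range: tuple[float, float] = (0.10, 0.90)
    ccr_range: tuple[float, float] = (0.10, 0.75)
    ewt_range: tuple[float, float] = (0.15, 0.70)
    # geography
    n_subregions: int = 21
    forest_margin_px: int = 2
    n_clearings: int = 2
    clearing_size_px: tuple[int, int] = (8, 16)
    # acquisitions (3 early-summer dates; >= 3 August dates x 4 years)
    n_diversity_dates: int = 3
    years: int = 4
    n_august_dates: int = 5
    # water status and the diversity->response linkage
    ndwi_base_range: tuple[float, float] = (0.38, 0.55)
    ndwi_base_smooth_px: float = 10.0
    rst0: float = -0.20
    beta_ric: float = 0.10
    gamma_eve: tuple[float, float] = (0.12, -0.12)
    rcv0: float = 0.15
    rsl0: float = -0.10
    beta_ric_rsl: float = 0.12
    gamma_eve_rsl: float = -0.04
    region_effect_sd: float = 0.02
    # sensor / scene realism
    noise_sd_reflectance: float = 0.001
    noise_sd_ndwi: float = 0.015
    cloud_fraction: float = 0.04
    shadow_fraction: float = 0.02
    anchors: dict = field(
        default_factory=lambda: {"B5": 0.08, "B4": 0.06, "B11": 0.12}
    )
    non_forest_targets: tuple[float, float, float, float] = (0.20, 0.05, 0.20, 0.20)
    # diversity truth computation
    kernel_radius_px: float = 3.0
    clip_pct: float = 0.1

    def validate(self) -> None:
        if self.rows < 32 or self.cols < 32:
            raise ConfigError("grid must be at least 32x32 pixels")
        if self.n_species < 1:
            raise ConfigError("need at least one species")
        if self.n_subregions < 1 or self.n_subregions > self.rows * self.cols:
            raise ConfigError("n_subregions must be in [1, n_pixels]")
        if self.years < 1 or self.n_august_dates < 1 or self.n_diversity_dates < 1:
            raise ConfigError("date counts must be positive")

    @property
    def n_dates(self) -> int:
        return self.n_diversity_dates + self.years * self.n_august_dates

    def date_tag(self, date_index: int) -> str:
        if date_index < 0 or date_index >= self.n_dates:
            raise ConfigError(f"date_index {date_index} out of range")
        if date_index < self.n_diversity_dates:
            return f"2017-06_div{date_index}"
        k = date_index - self.n_diversity_dates
        year, scene = divmod(k, self.n_august_dates)
        return f"{2017 + year}-08_s{scene}"


@dataclass
class LandscapeTruth:
    seed: int
    config: LandscapeConfig
    species_traits: np.ndarray       # (n_species, 3) in trait ranges
    patch_map: np.ndarray            # species label per pixel (0..n_species-1)
    subregion_map: np.ndarray        # 1..K
    forest_polygons: list
    forest_mask: np.ndarray          # bool
    trait_maps: np.ndarray           # (3, H, W) noiseless trait targets
    ndwi_base: np.ndarray
    fric: np.ndarray                 # truth richness (convex volume)
    feve: np.ndarray                 # truth evenness
    ric01: np.ndarray                # rescaled richness driving the linkage
    eve01: np.ndarray
    resistance: np.ndarray           # truth fractional responses
    recovery: np.ndarray
    resilience: np.ndarray
    ndwi_year_targets: np.ndarray    # (years, H, W)
    region_effects: dict             # response -> (K,) offsets

    @property
    def year_effects(self) -> np.ndarray:
        """Mean multiplicative NDWI factor of each year relative to year 1."""
        base = np.nanmean(self.ndwi_year_targets[0])
        return np.nanmean(self.ndwi_year_targets, axis=(1, 2)) / base


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream], int(extra)])


def _flood_fill_patches(cfg: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded multi-source flood fill; every round, unclaimed pixels adopt
    the label of a random already-claimed 4-neighbor."""
    H, W = cfg.rows, cfg.cols
    labels = np.full((H, W), -1, dtype=np.int32)
    n_seeds = cfg.n_species * cfg.seeds_per_species
    flat = rng.choice(H * W, size=min(n_seeds, H * W), replace=False)
    for s in range(cfg.n_species):
        pick = flat[s * cfg.seeds_per_species:(s + 1) * cfg.seeds_per_species]
        labels.ravel()[pick] = s
    shifts = ((1, 0), (-1, 0), (0, 1), (0, -1))
    while np.any(labels < 0):
        prio = rng.random((H, W))
        best_p = np.full((H, W), -1.0)
        best_l = np.full((H, W), -1, dtype=np.int32)
        for dr, dc in shifts:
            lab_n = np.roll(labels, (dr, dc), axis=(0, 1))
            pri_n = np.roll(prio, (dr, dc), axis=(0, 1))
            # forbid wrap-around
            if dr == 1:
                lab_n[0, :] = -1
            elif dr == -1:
                lab_n[-1, :] = -1
            if dc == 1:
                lab_n[:, 0] = -1
            elif dc == -1:
                lab_n[:, -1] = -1
            cand = (labels < 0) & (lab_n >= 0) & (pri_n > best_p)
            best_p[cand] = pri_n[cand]
            best_l[cand] = lab_n[cand]
        grow = best_l >= 0
        labels[grow] = best_l[grow]
    return labels


def _voronoi_labels(cfg: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    H, W = cfg.rows, cfg.cols
    K = cfg.n_subregions
    flat = rng.choice(H * W, size=K, replace=False)
    sr, sc = np.divmod(flat, W)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    d2 = (rr[:, :, None] - sr) ** 2 + (cc[:, :, None] - sc) ** 2
    return np.argmin(d2, axis=2).astype(np.int32) + 1


def _forest_geometry(cfg: LandscapeConfig, rng: np.random.Generator):
    H, W, ps = cfg.rows, cfg.cols, cfg.pixel_size
    m = cfg.forest_margin_px
    outer = box(m * ps, m * ps, (W - m) * ps, (H - m) * ps)
    holes = []
    lo, hi = cfg.clearing_size_px
    for _ in range(cfg.n_clearings):
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        c0 = int(rng.integers(m + 1, max(m + 2, W - m - w - 1)))
        r0 = int(rng.integers(m + 1, max(m + 2, H - m - h - 1)))
        holes.append(box(c0 * ps, r0 * ps, (c0 + w) * ps, (r0 + h) * ps))
    geom = outer
    for hole in holes:
        geom = geom.difference(hole)
    polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
    mask = gridio.rasterize_polygons(polys, (H, W), ps)
    return polys, mask


def _smooth_field(shape, sigma, rng: np.random.Generator) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    f -= f.min()
    peak = f.max()
    return f / peak if peak > 0 else f


def _nanfill(arr: np.ndarray, fallback: float = 0.0) -> np.ndarray:
    out = np.array(arr, dtype=float)
    finite = np.isfinite(out)
    fill = float(np.median(out[finite])) if np.any(finite) else fallback
    out[~finite] = fill
    return out


def generate_truth(config: LandscapeConfig, seed: int) -> LandscapeTruth:
    """Build the full ground truth for one landscape realization."""
    cfg = config
    cfg.validate()
    H, W = cfg.rows, cfg.cols

    ranges = np.array([cfg.chl_range, cfg.ccr_range, cfg.ewt_range])
    sp_rng = _rng(seed, "species")
    species_traits = sp_rng.uniform(ranges[:, 0], ranges[:, 1], size=(cfg.n_species, 3))

    patch_map = _flood_fill_patches(cfg, _rng(seed, "patches"))
    subregion_map = _voronoi_labels(cfg, _rng(seed, "subregions"))
    forest_polygons, forest_mask = _forest_geometry(cfg, _rng(seed, "clearings"))

    jit_rng = _rng(seed, "jitter")
    trait_maps = species_traits[patch_map].transpose(2, 0, 1).copy()
    trait_maps += jit_rng.normal(0.0, cfg.trait_jitter_sd, size=trait_maps.shape)
    trait_maps = np.clip(trait_maps, ranges[:, 0, None, None], ranges[:, 1, None, None])

    fld_rng = _rng(seed, "field")
    lo, hi = cfg.ndwi_base_range
    ndwi_base = lo + (hi - lo) * _smooth_field((H, W), cfg.ndwi_base_smooth_px, fld_rng)

    # truth diversity on the noiseless traits, in analysis units
    masked_traits = np.where(forest_mask[None], trait_maps, np.nan)
    scaled = np.stack([
        rescale01(IndexRaster(masked_traits[i], t), cfg.clip_pct).masked()
        for i, t in enumerate(("CHL", "CCR", "EWT"))
    ])
    kern = circular_kernel(cfg.kernel_radius_px)
    div = map_functional_diversity(scaled, forest_mask, kern, mode="convex")

    def safe_rescale(arr, name):
        # a fully degenerate metric map (e.g. one species, no jitter) has
        # no valid evenness anywhere; the linkage then falls back on 0.5
        if not np.any(np.isfinite(arr)):
            return np.full(arr.shape, np.nan)
        return rescale01(IndexRaster(arr, name), cfg.clip_pct).masked()

    ric01 = safe_rescale(div.fric, "ric")
    eve01 = safe_rescale(div.feve, "eve")
    ric_f = _nanfill(ric01, 0.5)
    eve_f = _nanfill(eve01, 0.5)

    reg_rng = _rng(seed, "regions_fx")
    K = cfg.n_subregions
    region_effects = {
        name: reg_rng.normal(0.0, cfg.region_effect_sd, size=K)
        for name in ("resistance", "recovery", "resilience")
    }
    ridx = subregion_map - 1
    g1, g2 = cfg.gamma_eve
    rst = (cfg.rst0 + cfg.beta_ric * ric_f + g1 * eve_f + g2 * eve_f**2
           + region_effects["resistance"][ridx])
    rcv = cfg.rcv0 + region_effects["recovery"][ridx]
    rsl = (cfg.rsl0 + cfg.beta_ric_rsl * ric_f + cfg.gamma_eve_rsl * eve_f
           + region_effects["resilience"][ridx])

    n1 = ndwi_base
    targets = [n1, n1 * (1 + rst), n1 * (1 + rst) * (1 + rcv), n1 * (1 + rsl)]
    ndwi_year_targets = np.stack(targets[: cfg.years])

    return LandscapeTruth(
        seed=int(seed), config=cfg, species_traits=species_traits,
        patch_map=patch_map, subregion_map=subregion_map,
        forest_polygons=forest_polygons, forest_mask=forest_mask,
        trait_maps=trait_maps, ndwi_base=ndwi_base,
        fric=div.fric, feve=div.feve, ric01=ric01, eve01=eve01,
        resistance=rst, recovery=rcv, resilience=rsl,
        ndwi_year_targets=ndwi_year_targets, region_effects=region_effects,
    )


# ---------------------------------------------------------------------------
# scene rendering (index inversion)

def _invert_ratio(target: np.ndarray, anchor: float, name: str) -> np.ndarray:
    """Solve a / anchor - 1 = target for a (red-edge ratio index)."""
    a = anchor * (1.0 + target)
    _check_band(a, name)
    return a


def _invert_norm_diff(target: np.ndarray, anchor: float, name: str) -> np.ndarray:
    """Solve (a - anchor) / (a + anchor) = target for a."""
    bad = np.abs(1.0 - target) < 1e-6
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise GenerationError(f"{name} target at pixel ({r}, {c}) not invertible")
    a = anchor * (1.0 + target) / (1.0 - target)
    _check_band(a, name)
    return a


def _check_band(a: np.ndarray, name: str) -> None:
    bad = ~((a >= 0.0) & (a <= 1.0))
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise GenerationError(
            f"inverted band for {name} out of [0, 1] at pixel ({r}, {c})"
        )


def _top_k_mask(field: np.ndarray, k: int, exclude: np.ndarray | None = None) -> np.ndarray:
    out = np.zeros(field.shape, dtype=bool)
    if k <= 0:
        return out
    f = field.ravel().copy()
    if exclude is not None:
        f[exclude.ravel()] = -np.inf
    idx = np.argpartition(f, -k)[-k:]
    out.ravel()[idx] = True
    return out


def render_scene(truth: LandscapeTruth, date_index: int) -> ReflectanceScene:
    """Render one acquisition by inverting the index definitions.

    Band choices per pixel: B5 anchored, B7 from the CHL target; B4
    anchored, B3 from CCR; B11 anchored, B8A from EWT and B8 from the date's
    NDWI target.  Gaussian band noise and cloud/shadow patches (smooth
    random fields thresholded at the exact contamination count) are applied
    afterwards; all bands clipped to [0, 1].
    """
    cfg = truth.config
    tag = cfg.date_tag(date_index)
    rng = _rng(truth.seed, "render", date_index)
    H, W = cfg.rows, cfg.cols

    nf = ~truth.forest_mask
    chl = np.where(nf, cfg.non_forest_targets[0], truth.trait_maps[0])
    ccr = np.where(nf, cfg.non_forest_targets[1], truth.trait_maps[1])
    ewt = np.where(nf, cfg.non_forest_targets[2], truth.trait_maps[2])

    if date_index < cfg.n_diversity_dates:
        ndwi_t = truth.ndwi_base.copy()
    else:
        year = (date_index - cfg.n_diversity_dates) // cfg.n_august_dates
        ndwi_t = truth.ndwi_year_targets[year].copy()
    ndwi_t = ndwi_t + rng.normal(0.0, cfg.noise_sd_ndwi, size=(H, W))
    ndwi_t = np.where(nf, cfg.non_forest_targets[3], ndwi_t)

    b5 = np.full((H, W), cfg.anchors["B5"])
    b4 = np.full((H, W), cfg.anchors["B4"])
    b11 = np.full((H, W), cfg.anchors["B11"])
    b7 = _invert_ratio(chl, cfg.anchors["B5"], "CIre")
    b3 = _invert_norm_diff(ccr, cfg.anchors["B4"], "CCI")
    b8a = _invert_norm_diff(ewt, cfg.anchors["B11"], "NDII")
    b8 = _invert_norm_diff(ndwi_t, cfg.anchors["B11"], "NDWI")

    bands = {
        "B2": np.full((H, W), 0.03), "B3": b3, "B4": b4, "B5": b5,
        "B6": np.full((H, W), 0.25), "B7": b7, "B8": b8, "B8A": b8a,
        "B11": b11, "B12": np.full((H, W), 0.10),
    }
    if cfg.noise_sd_reflectance > 0:
        for name in BAND_ORDER:
            bands[name] = bands[name] + rng.normal(
                0.0, cfg.noise_sd_reflectance, size=(H, W)
            )

    n_cloud = int(round(cfg.cloud_fraction * H * W))
    n_shadow = int(round(cfg.shadow_fraction * H * W))
    cloud = _top_k_mask(gaussian_filter(rng.standard_normal((H, W)), 3.0), n_cloud)
    shadow = _top_k_mask(
        gaussian_filter(rng.standard_normal((H, W)), 3.0), n_shadow, exclude=cloud
    )
    for name in BAND_ORDER:
        b = bands[name]
        b[cloud] = 0.35 + 0.02 * rng.standard_normal(int(n_cloud))
        bands[name] = b
    bands["B2"][cloud] = 0.30
    dark = {"B2": 0.02, "B6": 0.02, "B12": 0.004, "B8A": 0.08}
    for name in BAND_ORDER:
        bands[name][shadow] = dark.get(name, 0.03)

    for name in BAND_ORDER:
        bands[name] = np.clip(bands[name], 0.0, 1.0)
    return ReflectanceScene(bands, cfg.pixel_size, tag)


# ---------------------------------------------------------------------------
# on-disk dataset

def save_truth(truth: LandscapeTruth, path: str | Path) -> None:
    def arr(a):
        return np.asarray(a).tolist()

    doc = {
        "seed": truth.seed,
        "config": dataclasses.asdict(truth.config),
        "species_traits": arr(truth.species_traits),
        "patch_map": arr(truth.patch_map),
        "subregion_map": arr(truth.subregion_map),
        "forest_polygons": [mapping(p) for p in truth.forest_polygons],
        "forest_mask": arr(truth.forest_mask.astype(int)),
        "trait_maps": arr(truth.trait_maps),
        "ndwi_base": arr(truth.ndwi_base),
        "fric": arr(truth.fric), "feve": arr(truth.feve),
        "ric01": arr(truth.ric01), "eve01": arr(truth.eve01),
        "resistance": arr(truth.resistance),
        "recovery": arr(truth.recovery),
        "resilience": arr(truth.resilience),
        "ndwi_year_targets": arr(truth.ndwi_year_targets),
        "region_effects": {k: arr(v) for k, v in truth.region_effects.items()},
    }
    Path(path).write_text(json.dumps(doc))


def load_truth(path: str | Path) -> LandscapeTruth:
    doc = json.loads(Path(path).read_text())
    cfg_doc = doc["config"]
    for key in ("chl_range", "ccr_range", "ewt_range", "ndwi_base_range",
                "gamma_eve", "clearing_size_px", "non_forest_targets"):
        cfg_doc[key] = tuple(cfg_doc[key])
    cfg = LandscapeConfig(**cfg_doc)
    a = np.asarray
    return LandscapeTruth(
        seed=doc["seed"], config=cfg,
        species_traits=a(doc["species_traits"]),
        patch_map=a(doc["patch_map"], dtype=np.int32),
        subregion_map=a(doc["subregion_map"], dtype=np.int32),
        forest_polygons=[shape(p) for p in doc["forest_polygons"]],
        forest_mask=a(doc["forest_mask"]).astype(bool),
        trait_maps=a(doc["trait_maps"]),
        ndwi_base=a(doc["ndwi_base"]),
        fric=a(doc["fric"]), feve=a(doc["feve"]),
        ric01=a(doc["ric01"]), eve01=a(doc["eve01"]),
        resistance=a(doc["resistance"]),
        recovery=a(doc["recovery"]),
        resilience=a(doc["resilience"]),
        ndwi_year_targets=a(doc["ndwi_year_targets"]),
        region_effects={k: a(v) for k, v in doc["region_effects"].items()},
    )


def generate_dataset(
    config: LandscapeConfig, seed: int, outdir: str | Path
) -> tuple[dict, list, np.ndarray, LandscapeTruth]:
    """Write the full multi-date input set consumable by the pipeline.

    Returns (scenes by date tag, forest polygons, subregion map, truth).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "scenes").mkdir(exist_ok=True)
    truth = generate_truth(config, seed)
    scenes = {}
    for di in range(config.n_dates):
        sc = render_scene(truth, di)
        scenes[sc.date_tag] = sc
        gridio.write_raster(
            out / "scenes" / f"scene_{di:02d}.tif",
            sc.stack(),
            band_names=list(BAND_ORDER),
            pixel_size=config.pixel_size,
            tags={"date_tag": sc.date_tag, "date_index": di},
        )
    gridio.write_geojson(out / "forest.geojson", truth.forest_polygons)
    gridio.write_raster(
        out / "subregions.tif",
        truth.subregion_map.astype(np.int32),
        pixel_size=config.pixel_size,
        tags={"n_subregions": config.n_subregions},
    )
    save_truth(truth, out / "truth.json")
    return scenes, truth.forest_polygons, truth.subregion_map, truth
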