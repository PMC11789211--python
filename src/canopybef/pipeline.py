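"""End-to-end pipeline: simulate -> indices -> mask -> diversity ->
response -> analyze, with a content-hashed manifest for resumable runs.

Every stage is disk-to-disk inside one run directory, so a stage whose
outputs already exist with matching hashes can be skipped on resume and
downstream stages recomputed after deleting an intermediate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gridio
from .bef_regression import (
    TERM_SETS,
    conservative_f,
    equal_range_bins,
    filter_small_bins,
    fit_combined,
    fit_univariate,
    region_correct,
    stratified_table,
)
from .drought_response import drought_responses, median_composite
from .functional_diversity import circular_kernel, map_functional_diversity
from .masking import build_forest_mask, cloudfree_mask, exclude_edge_patches
from .spectral_indices import (
    BAND_ORDER,
    IndexRaster,
    ReflectanceScene,
    compute_index,
    rescale01,
)
from .synthetic_landscape import LandscapeConfig, generate_dataset

log = logging.getLogger("canopybef")

STAGES = ("simulate", "indices", "mask", "diversity", "response", "analyze")

RESPONSES = ("rst", "rcv", "rsl")
RESPONSE_FIELDS = {"rst": "resistance", "rcv": "recovery", "rsl": "resilience"}


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    generator: LandscapeConfig = field(default_factory=LandscapeConfig)
    kernel_radius_px: float = 3.0
    fd_mode: str = "alpha_adaptive"
    alpha: float | None = None
    weighted_feve: bool = True
    min_points_fric: int = 4
    min_points_feve: int = 3
    min_weight_frac: float = 0.5
    c_ndvi: float = 3.0
    c_shadow: float = 3.0
    min_votes: int = 2
    min_patch_px: int = 28
    erosion_px: int = 0
    eps: float = 1e-3
    clip_pct: float = 0.1
    n_bins_univariate: int = 1000
    n_bins_combined: int = 20
    min_bin_frac: float = 0.01

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if isinstance(gen, dict):
            for key in ("chl_range", "ccr_range", "ewt_range", "ndwi_base_range",
                        "gamma_eve", "clearing_size_px", "non_forest_targets"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            gen = LandscapeConfig(**gen)
        cfg = cls(generator=gen, **d)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def validate(self) -> None:
        self.generator.validate()
        if self.fd_mode not in ("convex", "alpha", "alpha_adaptive"):
            raise ValueError(f"unknown fd_mode {self.fd_mode!r}")
        if self.fd_mode == "alpha" and self.alpha is None:
            raise ValueError("fixed-alpha mode needs alpha")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")


# ---------------------------------------------------------------------------
# pure stage logic (arrays in, arrays out)

def composite_traits(scenes: list[ReflectanceScene]) -> np.ndarray:
    """(3, H, W) median composite of CIre, CCI, NDII over the diversity
    dates, honoring each scene's cloud-free flag."""
    traits = []
    for trait_index in ("CIre", "CCI", "NDII"):
        per_scene = []
        for sc in scenes:
            idx = compute_index(sc, trait_index)
            ok = cloudfree_mask(sc).values & idx.valid
            vals = idx.masked()
            vals[~ok] = np.nan
            per_scene.append(IndexRaster(vals, trait_index))
        traits.append(median_composite(per_scene, trait_index).ndwi)
    return np.stack(traits)


def diversity_from_traits(traits: np.ndarray, mask: np.ndarray, cfg: "RunConfig"):
    """Rescale composited traits within the mask and map FRic / FEve."""
    scaled = [
        rescale01(IndexRaster(np.where(mask, traits[i], np.nan), n), cfg.clip_pct).masked()
        for i, n in enumerate(("CHL", "CCR", "EWT"))
    ]
    kern = circular_kernel(cfg.kernel_radius_px)
    return map_functional_diversity(
        np.stack(scaled), mask, kern,
        mode=cfg.fd_mode, alpha=cfg.alpha,
        min_points_fric=cfg.min_points_fric,
        min_points_feve=cfg.min_points_feve,
        min_weight_frac=cfg.min_weight_frac,
        weighted_feve=cfg.weighted_feve,
    )


def responses_from_scenes(
    scenes_by_year: list[list[ReflectanceScene]], mask: np.ndarray, cfg: "RunConfig"
):
    """Yearly median NDWI composites and the three change-ratio maps."""
    if len(scenes_by_year) < 4:
        raise ValueError(
            "drought responses need 4 yearly composites "
            f"(got {len(scenes_by_year)} years)"
        )
    composites = []
    for y, group in enumerate(scenes_by_year[:4]):
        rasters = []
        for sc in group:
            idx = compute_index(sc, "NDWI")
            ok = cloudfree_mask(sc).values & idx.valid
            vals = idx.masked()
            vals[~ok] = np.nan
            rasters.append(IndexRaster(vals, "NDWI"))
        composites.append(median_composite(rasters, f"year{y + 1}"))
    resp = drought_responses(*composites, eps=cfg.eps)
    stack = np.stack([resp.resistance, resp.recovery, resp.resilience])
    stack[:, ~np.asarray(mask, bool)] = np.nan
    return stack, composites


def analyze_maps(
    fric: np.ndarray,
    feve: np.ndarray,
    region_map: np.ndarray,
    responses: dict[str, np.ndarray],
    mask: np.ndarray,
    cfg: "RunConfig",
) -> dict:
    """Binned univariate fits plus the combined stratified models.

    Returns a dict with the rescaled metric maps, the univariate fit
    summaries, the stratified table, per-response ANOVA tables (with F2)
    and region-corrected values.
    """
    ric01 = rescale01(IndexRaster(np.where(mask, fric, np.nan), "ric"), cfg.clip_pct).masked()
    eve01 = rescale01(IndexRaster(np.where(mask, feve, np.nan), "eve"), cfg.clip_pct).masked()

    univariate = {}
    for metric_name, metric in (("ric", ric01), ("eve", eve01)):
        for rname, rmap in responses.items():
            series = equal_range_bins(metric, cfg.n_bins_univariate, rmap)
            kept = filter_small_bins(series, cfg.min_bin_frac)
            entry = {
                "n_bins_surviving": int(len(kept.table)),
                "value_range": [
                    float(kept.table["center"].min()),
                    float(kept.table["center"].max()),
                ] if len(kept.table) else None,
            }
            try:
                fit = fit_univariate(kept)
                entry.update({
                    "chosen_form": fit.chosen,
                    "params": {k: float(v) for k, v in fit.params.items()},
                    "forms": fit.reports.reset_index().to_dict("records"),
                })
            except ValueError as exc:
                entry["error"] = str(exc)
            univariate[f"{rname}~{metric_name}"] = entry

    table = stratified_table(
        ric01, eve01, region_map, responses, valid=mask, n_bins=cfg.n_bins_combined
    )
    anovas = {}
    corrected = {}
    for rname in responses:
        anovas[rname] = conservative_f(fit_combined(table, rname))
        corrected[rname] = region_correct(table, rname)
    return {
        "ric01": ric01,
        "eve01": eve01,
        "univariate": univariate,
        "table": table,
        "anovas": anovas,
        "corrected": corrected,
    }


def simulate_and_analyze(cfg: RunConfig) -> dict:
    """Run the whole pipeline in memory on one synthetic landscape.

    Convenience for simulation experiments: returns the ground truth plus
    every intermediate the disk pipeline would write.
    """
    from .synthetic_landscape import generate_truth, render_scene

    cfg.validate()
    gcfg = cfg.generator
    truth = generate_truth(gcfg, cfg.seed)
    div_scenes = [render_scene(truth, i) for i in range(gcfg.n_diversity_dates)]
    traits = composite_traits(div_scenes)
    mask = build_forest_mask(
        div_scenes, truth.forest_polygons, cfg.c_ndvi, cfg.c_shadow,
        cfg.min_votes, gcfg.pixel_size,
    )
    mask = exclude_edge_patches(mask, cfg.min_patch_px, cfg.erosion_px)
    div = diversity_from_traits(traits, mask.values, cfg)
    scenes_by_year = [
        [
            render_scene(truth, gcfg.n_diversity_dates + y * gcfg.n_august_dates + s)
            for s in range(gcfg.n_august_dates)
        ]
        for y in range(gcfg.years)
    ]
    resp_stack, composites = responses_from_scenes(scenes_by_year, mask.values, cfg)
    responses = {k: resp_stack[i] for i, k in enumerate(RESPONSES)}
    analysis = analyze_maps(
        div.fric, div.feve, truth.subregion_map, responses, mask.values, cfg
    )
    return {
        "truth": truth,
        "mask": mask,
        "traits": traits,
        "diversity": div,
        "responses": responses,
        "composites": composites,
        **analysis,
    }


# ---------------------------------------------------------------------------
# stage implementations (disk-to-disk inside the run directory)

def _read_scene(path: Path) -> ReflectanceScene:
    arr, meta = gridio.read_raster(path)
    names = meta["band_names"] or list(BAND_ORDER)
    return ReflectanceScene(
        {n: arr[i] for i, n in enumerate(names)},
        meta["pixel_size"],
        meta["tags"].get("date_tag", path.stem),
    )


def _scene_paths(out: Path, cfg: RunConfig) -> list[Path]:
    return [out / "scenes" / f"scene_{i:02d}.tif" for i in range(cfg.generator.n_dates)]


def _stage_simulate(out: Path, cfg: RunConfig) -> list[Path]:
    generate_dataset(cfg.generator, cfg.seed, out)
    return _scene_paths(out, cfg) + [
        out / "forest.geojson", out / "subregions.tif", out / "truth.json",
    ]


def _stage_indices(out: Path, cfg: RunConfig) -> list[Path]:
    gcfg = cfg.generator
    scenes = [_read_scene(p) for p in _scene_paths(out, cfg)[: gcfg.n_diversity_dates]]
    traits = composite_traits(scenes)
    path = out / "traits_raw.tif"
    gridio.write_raster(
        path, traits, band_names=["CIre", "CCI", "NDII"],
        pixel_size=gcfg.pixel_size, tags={"composite": "median of diversity dates"},
    )
    return [path]


def _stage_mask(out: Path, cfg: RunConfig) -> list[Path]:
    gcfg = cfg.generator
    scenes = [_read_scene(p) for p in _scene_paths(out, cfg)[: gcfg.n_diversity_dates]]
    polys = gridio.read_geojson(out / "forest.geojson")
    mask = build_forest_mask(
        scenes, polys, cfg.c_ndvi, cfg.c_shadow, cfg.min_votes, gcfg.pixel_size
    )
    mask = exclude_edge_patches(mask, cfg.min_patch_px, cfg.erosion_px)
    path = out / "forest_mask.tif"
    gridio.write_raster(
        path, mask.values.astype(np.uint8), pixel_size=gcfg.pixel_size,
        tags={"provenance": mask.provenance, "count_valid": mask.count_valid},
    )
    side = out / "mask_provenance.json"
    side.write_text(json.dumps({
        "provenance": mask.provenance,
        "count_valid": mask.count_valid,
        "area_km2": mask.area_km2(gcfg.pixel_size),
    }))
    return [path, side]


def _load_mask(out: Path) -> np.ndarray:
    arr, _ = gridio.read_raster(out / "forest_mask.tif")
    return arr[0].astype(bool)


def _stage_diversity(out: Path, cfg: RunConfig) -> list[Path]:
    arr, _ = gridio.read_raster(out / "traits_raw.tif")
    mask = _load_mask(out)
    div = diversity_from_traits(arr, mask, cfg)
    path = out / "diversity.tif"
    gridio.write_raster(
        path, np.stack([div.fric, div.feve, div.n_points]),
        band_names=["fric", "feve", "n_points"],
        pixel_size=cfg.generator.pixel_size,
        tags={"radius_px": cfg.kernel_radius_px, "mode": cfg.fd_mode,
              "alpha": cfg.alpha, "weighted_feve": cfg.weighted_feve},
    )
    return [path]


def _stage_response(out: Path, cfg: RunConfig) -> list[Path]:
    gcfg = cfg.generator
    mask = _load_mask(out)
    paths = _scene_paths(out, cfg)
    scenes_by_year = [
        [
            _read_scene(p)
            for p in paths[
                gcfg.n_diversity_dates + y * gcfg.n_august_dates:
                gcfg.n_diversity_dates + (y + 1) * gcfg.n_august_dates
            ]
        ]
        for y in range(gcfg.years)
    ]
    stack, _ = responses_from_scenes(scenes_by_year, mask, cfg)
    path = out / "responses.tif"
    gridio.write_raster(
        path, stack, band_names=["resistance", "recovery", "resilience"],
        pixel_size=gcfg.pixel_size, tags={"eps": cfg.eps},
    )
    return [path]


def _stage_analyze(out: Path, cfg: RunConfig) -> list[Path]:
    div, dmeta = gridio.read_raster(out / "diversity.tif")
    resp, _ = gridio.read_raster(out / "responses.tif")
    sub, _ = gridio.read_raster(out / "subregions.tif")
    region_map = sub[0].astype(int)
    mask = _load_mask(out)
    responses = {k: resp[i] for i, k in enumerate(RESPONSES)}
    result = analyze_maps(div[0], div[1], region_map, responses, mask, cfg)
    table = result["table"]
    strat_path = out / "stratified.csv"
    table.data.to_csv(strat_path, index=False)

    outputs = [strat_path]
    combined = {}
    for rname in RESPONSES:
        anova = result["anovas"][rname]
        apath = out / f"anova_{rname}.csv"
        anova.table.to_csv(apath, index=False)
        outputs.append(apath)
        combined[rname] = {
            "terms": json.loads(anova.table.to_json(orient="records")),
            "total_ss": anova.total_ss,
            "resid_ss": anova.resid_ss,
            "resid_df": anova.resid_df,
            "model_r2": anova.model_r2,
            "ss_percent": {
                row["term"]: 100.0 * row["r2_inc"]
                for _, row in anova.table.iterrows()
            },
            "coefficients": {k: float(v) for k, v in anova.coefficients.items()},
            "rank_deficient": anova.rank_deficient,
            "formula_terms": list(TERM_SETS[rname]),
        }
    corr = table.nonempty()[["ric_bin", "eve_bin", "region", "ric", "eve", "N"]].copy()
    for rname, series in result["corrected"].items():
        corr[f"{rname}_corrected"] = series
    cpath = out / "region_corrected.csv"
    corr.to_csv(cpath, index=False)
    outputs.append(cpath)

    analysis = {"univariate": result["univariate"], "combined": combined}
    jpath = out / "analysis.json"
    jpath.write_text(json.dumps(analysis, indent=1, default=float))
    return [jpath] + outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "indices": _stage_indices,
    "mask": _stage_mask,
    "diversity": _stage_diversity,
    "response": _stage_response,
    "analyze": _stage_analyze,
}


def run_pipeline(
    config: RunConfig,
    stages: tuple[str, ...] | None = None,
    resume: bool = False,
) -> dict:
    """Execute the pipeline stages in order and write a hashed manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1))
    to_run = STAGES if stages is None else tuple(s for s in STAGES if s in stages)
    manifest_path = out / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        previous = {s["name"]: s for s in old.get("stages", [])}
    manifest = {"config": config.to_dict(), "stages": []}
    for name in STAGES:
        if name not in to_run:
            if name in previous:
                manifest["stages"].append(previous[name])
            continue
        prev = previous.get(name)
        if resume and prev is not None:
            ok = all(
                Path(p).exists() and gridio.sha256_file(p) == h
                for p, h in prev["outputs"].items()
            )
            if ok:
                log.info("stage %s: outputs up to date, skipping", name)
                manifest["stages"].append(prev)
                continue
        t0 = time.perf_counter()
        log.info("stage %s: running", name)
        try:
            paths = _STAGE_FUNCS[name](out, config)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        entry = {
            "name": name,
            "outputs": {str(p): gridio.sha256_file(p) for p in paths},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        manifest["stages"].append(entry)
        manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def report(outdir: str | Path) -> dict:
    """Summarize a completed run into report.json.

    Contains diversity- and response-map statistics, the univariate fit
    table, the combined ANOVA with SS percentages and conservative F2, and
    the region-corrected scatter data location.
    """
    out = Path(outdir)
    needed = ["diversity.tif", "responses.tif", "analysis.json", "manifest.json"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing {missing}")
    div, _ = gridio.read_raster(out / "diversity.tif")
    resp, _ = gridio.read_raster(out / "responses.tif")
    analysis = json.loads((out / "analysis.json").read_text())

    def summarize(a):
        finite = a[np.isfinite(a)]
        if finite.size == 0:
            return {"n": 0}
        return {
            "n": int(finite.size),
            "mean": float(finite.mean()),
            "min": float(finite.min()),
            "max": float(finite.max()),
        }

    doc = {
        "diversity": {"fric": summarize(div[0]), "feve": summarize(div[1])},
        "responses": {
            name: summarize(resp[i])
            for i, name in enumerate(("resistance", "recovery", "resilience"))
        },
        "univariate": analysis["univariate"],
        "combined": analysis["combined"],
        "region_corrected_csv": "region_corrected.csv",
    }
    (out / "report.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc
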