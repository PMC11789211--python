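# canopybef

Satellite-derived **canopy functional diversity** and **forest drought
response**, and the regression machinery to relate the two — a
biodiversity–ecosystem-functioning (BEF) analysis for 20 m multispectral
reflectance grids, with a synthetic-landscape generator so the entire
pipeline is testable end to end without any satellite downloads.

The package is aimed at remote-sensing ecologists who want a reproducible,
fully-inspectable implementation of the trait-based diversity mapping +
drought change-ratio + binned weighted-regression workflow, either to run
on their own Sentinel-2-style band stacks or to study the method's behavior
under controlled synthetic conditions.

## The method

**Trait proxies.** Three leaf ecophysiological traits are mapped per pixel
from surface reflectance ρ (band centers in nm):

- chlorophyll content (CHL): CIre = ρ₇₈₃/ρ₇₀₄ − 1 (bands B7, B5)
- carotenoid/chlorophyll ratio (CCR): CCI = (ρ₅₆₀ − ρ₆₆₄)/(ρ₅₆₀ + ρ₆₆₄) (B3, B4)
- equivalent water thickness (EWT): NDII = (ρ₈₆₅ − ρ₁₆₁₄)/(ρ₈₆₅ + ρ₁₆₁₄) (B8A, B11)

Each index map is a median composite over three early-summer acquisitions,
masked by a cloud/shadow/forest chain (B2 < 5% and B8A > 15% reflectance;
polygon clipping; robust median−c·MAD screens on NDVI and the B6/B12 dark
bands; 2-of-3 multi-date voting), and rescaled to [0, 1] with 0.1% tail
clipping.

**Functional diversity.** For every forest pixel, the trait triples of its
neighbors under a circular kernel (radius 3 px = 60 m; ≈28.3 weighted
pixels ≈ 1.131 ha) form a cloud in 3-D trait space:

- *functional richness* (FRic) — volume of the cloud's hull (concave
  α-shape by default, convex hull as the deterministic reference mode);
- *functional evenness* (FEve) — Villéger's regularity index on the
  Euclidean minimum spanning tree, FEve = [Σ min(PEWₗ, 1/(S−1)) − 1/(S−1)]
  / [1 − 1/(S−1)], with kernel area fractions as abundances.

**Drought response.** Canopy water status is NDWI = (ρ₈₃₃ − ρ₁₆₁₄)/(ρ₈₃₃ +
ρ₁₆₁₄) (B8, B11), composited as the per-year August median. Responses are
fractional change ratios between yearly composites: resistance
(year 1→2, into the drought), recovery (2→3), resilience (1→4).

**BEF regression.** Univariate: each diversity metric is cut into 1000
equal-range bins, responses averaged per bin, bins under 1% of the maximum
count dropped, and linear/quadratic/logarithmic weighted fits (weights =
pixel counts N) compared by AIC. Combined: pixels are stratified into 20 ×
20 diversity bins × K subregions (8400 strata at K = 21) and modelled by
weighted least squares with sequential (Type-I) sums of squares, e.g. in R
notation

    lm(terms(rst ~ logric + (eve + eve2) + REG
             + logric:REG + eve:REG + eve2:REG, keep.order = T), weight = N)

SS percentages are increments of multiple r² × 100; a conservative F-ratio
(F2) tests each diversity term against its subregion interaction; and a
subregion correction (region-fit residuals + weighted grand mean) yields
display-ready adjusted responses.

## Worked example

```python
from canopybef import LandscapeConfig, RunConfig, run_pipeline, report

gen = LandscapeConfig(rows=64, cols=64, n_subregions=8)
cfg = RunConfig(outdir="demo", seed=42, generator=gen,
                fd_mode="convex", min_patch_px=10)
run_pipeline(cfg)        # simulate -> indices -> mask -> diversity
                         #          -> response -> analyze
doc = report("demo")
```

On this 64×64 synthetic landscape the run prints (rounded):

```
fric:  mean 0.054, range 0.005–0.195   (rescaled-trait volume units)
feve:  mean 0.437, range 0.048–0.854
resistance:  mean −0.157   (15.7% NDWI loss into the drought year)
recovery:    mean +0.161
resilience:  mean −0.100
rst combined model: r² = 0.51, SS% = {logric 12.7, eve 0.6, eve² 0.4,
                    REG 34.2, logric:REG 1.6, eve:REG 0.6, eve²:REG 0.5}
coefficients: logric +0.0097, eve² −0.0096
```

The positive `logric` and negative `eve²` coefficients recover the signs of
the generator's diversity→response linkage: resistance improves with local
functional richness and peaks at intermediate evenness. The subregion term
(REG) absorbs the generated regional offsets, and the interaction terms stay
small because the generative linkage is the same in every subregion.

The same workflow is available from the shell:

```bash
canopybef run-all --config run.yaml --seed 42 --out demo
canopybef report --out demo
```

Every stage writes content-hashed outputs into a manifest, so `--resume`
recomputes only stages whose inputs changed.

## Layout

```
src/canopybef/
  synthetic_landscape.py   landscape truth + scene rendering (index inversion)
  spectral_indices.py      CIre/CCI/NDII/NDWI/NDVI, rescaling, resampling
  masking.py               cloud flags, robust thresholds, 2-of-3 voting
  functional_diversity.py  circular kernel, alpha-shape FRic, MST FEve
  drought_response.py      yearly NDWI composites, change ratios
  bef_regression.py        binning, weighted fits, sequential SS, F2
  pipeline.py              stage orchestration, manifests, reporting
  cli.py                   `canopybef` console script
docs/methods.md            model assumptions, parameters, limitations
```
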