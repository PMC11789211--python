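# Methods

This note documents the models implemented in `canopybef`, the choices made
where the design was genuinely open, what the synthetic landscapes do and
do not emulate, and the numerical conventions that matter for
reproducibility.

## Trait mapping and masking

Three spectral indices serve as trait proxies on a 20 m grid: the red-edge
chlorophyll index CIre (chlorophyll content), the carotenoid/chlorophyll
index CCI, and the normalized difference infrared index NDII (equivalent
water thickness). The three indices use disjoint band pairs, so their
measurement errors are largely independent — a prerequisite for treating
them as axes of a trait space. Pixels with an index denominator below 1e-9
in magnitude are invalid rather than infinite.

The masking chain reproduces a standard optical pre-processing recipe:

* **cloud/shadow flag** — a pixel is cloud- and cloud-shadow-free iff
  B2 < 0.05 and B8A > 0.15 (strict inequalities, reflectance fractions);
* **forest polygons** — pixels whose center falls inside the forest layer;
* **robust screens** — within the polygon area, lower thresholds are set at
  median − c·MAD (default c = 3, configurable) for NDVI (gaps, dead
  canopies) and for B6 and B12 (cast shadow). A pixel is *excluded* when it
  falls strictly below a threshold; consequently a zero-dispersion sample
  (MAD = 0) excludes nothing, which keeps degenerate synthetic scenes and
  homogeneous real scenes usable. "Median outlier" has no canonical
  definition; median ± c·MAD is monotone in c, so users can match empirical
  thresholds from other processing chains by adjusting one constant.
* **2-of-3 voting** — the final mask keeps pixels valid in at least
  `min_votes` (default 2) of the three early-summer scenes, equivalent to a
  mean of the boolean validity layers ≥ 2/3;
* **edge exclusion** — 8-connected patches below `min_patch_px` (default
  28 px, one kernel area) are dropped and an optional erosion removes edge
  pixels, because windowed diversity values on small patches are dominated
  by boundary geometry.

Index maps are rescaled to [0, 1] with `clip_pct` = 0.1% tails mapped to
0/1 (linearly interpolated empirical percentiles). The same operation, with
the same default, is applied both to trait maps before diversity
calculation and to diversity maps before binning; whether those two
rescales share the tail-clipping convention was an open choice and a single
configurable operation is the simplest defensible answer. A constant raster
rescales to 0.5 everywhere rather than erroring: zero trait dispersion then
propagates to zero richness, which is the scientifically correct downstream
result.

## Functional diversity

The moving window is a circle of radius 3 px (60 m) around the center
pixel; each cell's weight is the exact area fraction of its unit square
inside the circle (cell/circle intersection geometry, not subsampling).
The weights of the radius-3 kernel sum to 28.27 px ≈ 1.131 ha at 20 m.
A window is reported only if its valid neighbors carry ≥ 50% of the total
kernel weight, suppressing residual edge effects beyond the patch
exclusion.

**FRic** is the volume of the window's trait cloud hull. Default is a
concave 3-D α-shape: the union of Delaunay tetrahedra with circumradius
≤ α, with α chosen per window as 2× the mean branch length of the cloud's
minimum spanning tree. The adaptive rule keeps hulls connected across
windows of very different dispersion; a fixed α and the convex hull are
selectable, and the convex mode doubles as a deterministic oracle (it is
also what the synthetic generator uses for its truth maps and what the
recovery experiment runs, since its volumes are closed-form checkable and
considerably faster). FRic ignores abundances; windows with fewer than 4
points (or a coplanar cloud) return invalid (respectively 0).

**FEve** is Villéger's evenness on the Euclidean MST of the cloud: for
branch *l* joining points *i, j*, EW_l = d(i,j)/(w_i + w_j), PEW_l =
EW_l/ΣEW, and FEve = [Σ min(PEW_l, 1/(S−1)) − 1/(S−1)]/[1 − 1/(S−1)] ∈
[0, 1]. Kernel area fractions serve as the abundances w by default; equal
weights are selectable (`weighted_feve=False`), since with equal weights
the abundance terms cancel. The MST is Prim's algorithm with ties broken by
lowest point index, making maps bit-reproducible across platforms; the map
code runs a vectorized batch Prim over windows and computes pairwise
distances through the Gram matrix (clipped at zero before the square root),
which is algebraically identical to direct differences and markedly faster
on memory-bandwidth-limited hosts.

## Drought response

Yearly canopy water status is the per-pixel median NDWI over that year's
August scenes (median compositing also rejects residual cloud artifacts).
Responses are fractional change ratios — resistance (year 1→2), recovery
(2→3), resilience (1→4); the second post-drought year avoids resilience
being a linear combination of resistance and recovery. Ratios are invalid
where |baseline NDWI| < ε (default 1e-3): percent change explodes near a
zero baseline. Responses are stored as fractions and converted to percent
only in reports.

## Regression

Univariate fits operate on 1000 equal-range bins of the rescaled metric
([i/n, (i+1)/n), last bin closed), with per-bin mean response and count N.
Bins with N < 1% of the maximum bin count are dropped (boundary count
kept). Candidate forms — linear, quadratic, logarithmic — are fitted by
weighted least squares with weights N and compared by AIC computed from the
Gaussian log-likelihood with N treated as frequency weights (N are pixel
counts, so frequency weighting is the consistent convention). The log form
uses log(x + δ) with δ = half a bin width, because the lowest bin center
can be arbitrarily close to zero; it is skipped with a warning if the
shifted predictor is not positive.

The combined analysis stratifies pixels into 20 × 20 diversity bins × K
subregions; empty strata are kept as N = 0 rows for accounting and excluded
from fitting. Predictors enter as bin-center values. Terms enter the
weighted model in a fixed order (richness term, evenness terms, subregion,
then diversity×subregion interactions), and each term's sequential (Type-I)
SS is the drop in weighted residual SS when its columns join the design —
so term SS + residual SS = total SS exactly, and r² increments sum to the
model r². Rank-deficient terms receive the SS of their estimable subspace
and are flagged. F tests use the residual mean square; the conservative F2
divides each diversity main-effect MS by its subregion-interaction MS (the
fixed-model analogue of declaring the interaction random), with the
interaction's df as denominator df — the df convention for F2 p-values was
unspecified, and (df_term, df_interaction) is the standard quasi-F choice.
P-values are upper F-tail probabilities with no multiplicity adjustment.
Subregion correction refits the response on subregion indicators (weighted)
and adds the residuals to the weighted grand mean, equalizing regional
means while preserving the overall level.

## Synthetic landscapes

The generator emulates the *structure* of the study data so every stage has
ground truth:

* species patches from seeded multi-source flood fill (default 8 species ×
  6 seeds), giving spatially varying local richness with patchy mixed
  stands;
* per-pixel trait triples = species values (drawn uniformly inside
  realistic index ranges) + within-species Gaussian jitter (default sd
  0.03 — within-crown/illumination variation at 20 m; its true magnitude
  is not well constrained, so it is a parameter);
* subregions as K nearest-seed (Voronoi) labels; forest as a margin-inset
  rectangle with rectangular clearings, shipped as GeoJSON polygons;
* a smooth baseline NDWI field (0.38–0.55), and four yearly NDWI levels
  encoding dip → rebound → partial relapse;
* the diversity→response linkage: each pixel's drought-year NDWI drop is
  linear in *rescaled* local richness (slope `beta_ric` = 0.10) and
  quadratic in rescaled evenness (`gamma_eve` = (0.12, −0.12), a hump
  peaking mid-range), plus per-subregion offsets (sd 0.02); resilience
  carries its own linear linkage (`beta_ric_rsl` = 0.12, evenness slope
  −0.04). Defining the linkage on the rescaled truth-diversity maps (the
  generator computes them with the package's own kernel, in convex mode, on
  the noiseless traits) puts the generative coefficients in the same units
  the regression stage estimates, making parameter recovery a meaningful
  check. Response magnitudes (base drop −0.20, recovery +0.15, resilience
  −0.10) reproduce the qualitative 2018-drought trajectory; they are
  configurable, not calibrated to any particular scene.
* scenes rendered by *inverting* the index definitions: one band of each
  pair is anchored (B5 = 0.08, B4 = 0.06, B11 = 0.12 — mid-range forest
  reflectances that keep every inversion inside [0, 1]) and the other
  solved for the target; Gaussian band noise (sd 0.001, white radiometric
  noise at the level of a high-SNR spaceborne imager), an NDWI
  scene-to-scene wobble (sd 0.015, standing in for phenology/illumination
  variation between August acquisitions), and cloud/shadow patches
  (smoothed random fields thresholded at the exact contamination count;
  defaults 4% + 2%) are added afterwards.

All randomness flows from one root seed through named substreams, so
identical (config, seed) produces bit-identical rasters and manifests.

What the generator does **not** emulate: radiative-transfer band
covariance, atmospheric residuals (spatially correlated errors),
topographic illumination, phenology, species spatial autocorrelation beyond
patchiness, or secondary drought agents (e.g. bark beetle). Passing tests
therefore demonstrate correctness of the *computational chain* and
recoverability of effects under known conditions — not that the method is
unbiased on real imagery, where correlated errors between the shared-band
indices (NDII/NDWI both use B11) and between years remain a substantive
caveat.

## Problem sizes and numerical conventions

The recovery experiment runs 100 seeds of the full pipeline on 128 × 128
landscapes (the package's standard simulation size; ~5 s per seed in convex
mode). Unit tests use 32–64 px grids. Tolerances: index inversion and
oracle equivalence at 1e-9; SS conservation at 1e-8 relative; percentile
and hull computations in float64 throughout. Degenerate inputs follow the
conventions above (constant rasters → 0.5; coplanar clouds → FRic 0;
identical points → FEve invalid; empty strata → excluded from fits).

A known bias worth stating: because the pipeline *measures* diversity from
noisy scenes and then rescales empirically, its richness axis is a slightly
stretched/attenuated version of the truth axis, so recovered slopes carry a
small (~5%) errors-in-variables bias at the default noise levels. Sign
recovery is unaffected; aggregate slope recovery stays within two typical
standard errors.
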