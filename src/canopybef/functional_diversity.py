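"""Moving-window functional richness and evenness in 3-D trait space.

Each masked pixel's neighborhood is the set of valid pixels under a circular
kernel (default radius 3 px = 60 m on a 20 m grid) whose weights are the
area fraction of each cell inside the circle.  The neighborhood's trait
triples (CHL, CCR, EWT in rescaled [0, 1] units) form a 3-D point cloud:

* functional richness (FRic) is the volume of the cloud's hull — the convex
  hull, or a concave alpha-shape (tetrahedra of the Delaunay complex with
  circumradius <= alpha) that is less outlier-sensitive;
* functional evenness (FEve) is the Villeger regularity index on the
  Euclidean minimum spanning tree: branch l joining points i, j contributes
  ``EW_l = d(i, j) / (w_i + w_j)``, ``PEW_l = EW_l / sum EW``, and
  ``FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))``.

The MST is Prim's algorithm with ties broken by lowest point index, so maps
are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from shapely.geometry import Point, box

MODES = ("convex", "alpha", "alpha_adaptive")

#: adaptive alpha = this factor times the mean MST branch length
ADAPTIVE_ALPHA_FACTOR = 2.0


# ---------------------------------------------------------------------------
# circular kernel

@dataclass
class CircularKernel:
    radius_px: float
    weights: np.ndarray  # (2r+1, 2r+1) area fractions in [0, 1]

    @property
    def weight_sum(self) -> float:
        return float(self.weights.sum())

    def area_ha(self, pixel_size: float = 20.0) -> float:
        return self.weight_sum * pixel_size**2 / 1e4

    def offsets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(drow, dcol, weight) for every cell with positive weight."""
        r = self.weights.shape[0] // 2
        dr, dc = np.nonzero(self.weights > 0)
        return dr - r, dc - r, self.weights[dr, dc]


def circular_kernel(radius_px: float = 3.0) -> CircularKernel:
    """Area-fraction weights of a circle of ``radius_px`` centered on the
    middle cell's midpoint (exact cell/circle intersection geometry).

    For radius 3 the weights sum to ~28.27 pixels (~1.131 ha at 20 m).
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    r_cells = int(np.ceil(radius_px + 0.5))
    size = 2 * r_cells + 1
    circle = Point(0.0, 0.0).buffer(radius_px, quad_segs=1024)
    w = np.zeros((size, size))
    for i in range(size):
        for j in range(size):
            cy = i - r_cells
            cx = j - r_cells
            cell = box(cx - 0.5, cy - 0.5, cx + 0.5, cy + 0.5)
            w[i, j] = cell.intersection(circle).area
    # fully interior cells are exact by construction; snap tiny slivers
    w[w < 1e-12] = 0.0
    # trim all-zero border rings so the array is as tight as possible
    keep = np.flatnonzero(w.sum(axis=0) + w.sum(axis=1) > 0)
    lo, hi = keep.min(), keep.max()
    pad = max(lo, size - 1 - hi)
    if pad > 0 and size - 2 * pad >= 1:
        w = w[pad:size - pad, pad:size - pad]
    return CircularKernel(radius_px, w)


# ---------------------------------------------------------------------------
# point-set metrics

@dataclass
class TraitPointSet:
    points: np.ndarray          # (N, 3)
    weights: np.ndarray | None = None
    center: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.weights is None:
            self.weights = np.ones(len(self.points))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume of the convex hull; 0 for degenerate (coplanar or fewer) sets."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0


def _tet_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized)."""
    a = pts[simplices[:, 0]]
    rel = pts[simplices[:, 1:]] - a[:, None, :]          # (m, 3, 3)
    sq = np.einsum("mij,mij->mi", rel, rel)              # |v_k|^2
    det = np.linalg.det(rel)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-14
    if np.any(ok):
        centers = np.linalg.solve(rel[ok], (sq[ok] / 2.0)[..., None])[..., 0]
        radii[ok] = np.sqrt(np.einsum("mi,mi->m", centers, centers))
    return radii


def _tet_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    rel = pts[simplices[:, 1:]] - a[:, None, :]
    return np.abs(np.linalg.det(rel)) / 6.0


def alpha_shape_volume(points: np.ndarray, alpha: float) -> float:
    """Volume of the 3-D alpha-shape: sum of Delaunay tetrahedra whose
    circumradius is at most ``alpha``.  ``alpha = inf`` is the convex hull."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        return 0.0
    if not np.isfinite(alpha):
        return convex_hull_volume(pts)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return 0.0
    radii = _tet_circumradii(pts, tri.simplices)
    keep = radii <= alpha
    if not np.any(keep):
        return 0.0
    return float(_tet_volumes(pts, tri.simplices[keep]).sum())


def _batch_prim(dist: np.ndarray, valid: np.ndarray):
    """Vectorized Prim's MST over a batch of point sets.

    ``dist``: (C, S, S) pairwise distances; ``valid``: (C, S) membership.
    Returns ``(src, dst, d)`` arrays of shape (C, S-1); slots beyond each
    set's S_i - 1 edges hold d = inf.  Ties go to the lowest destination
    index, then to the earliest-grown source (deterministic).
    """
    C, S, _ = dist.shape
    big = np.inf
    d = dist.copy()
    d[~valid[:, :, None] | ~valid[:, None, :]] = big
    idx = np.arange(C)
    start = np.argmax(valid, axis=1)
    in_tree = np.zeros((C, S), dtype=bool)
    in_tree[idx, start] = True
    mind = d[idx, start, :].copy()
    mind[idx, start] = big
    src = np.broadcast_to(start[:, None], (C, S)).copy()
    e_src = np.full((C, S - 1), -1, dtype=np.int32)
    e_dst = np.full((C, S - 1), -1, dtype=np.int32)
    e_d = np.full((C, S - 1), big)
    for it in range(S - 1):
        j = np.argmin(mind, axis=1)
        dj = mind[idx, j]
        grown = np.isfinite(dj)
        e_src[grown, it] = src[idx, j][grown]
        e_dst[grown, it] = j[grown]
        e_d[grown, it] = dj[grown]
        in_tree[idx[grown], j[grown]] = True
        rows = d[idx, j, :]
        better = grown[:, None] & (rows < mind)
        src = np.where(better, j[:, None], src)
        mind = np.where(better, rows, mind)
        mind[in_tree] = big
    return e_src, e_dst, e_d


def mst_edges(points: np.ndarray):
    """Deterministic Euclidean MST of one point set: (src, dst, length)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n < 2:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))[None]
    valid = np.ones((1, n), dtype=bool)
    s, t, d = _batch_prim(dist, valid)
    keep = np.isfinite(d[0])
    return s[0][keep], t[0][keep], d[0][keep]


def _feve_from_edges(src, dst, d, weights, n_points: int) -> float:
    if n_points < 3:
        return np.nan
    total_len = d.sum()
    if total_len <= 0:
        return np.nan
    ew = d / (weights[src] + weights[dst])
    pew = ew / ew.sum()
    thr = 1.0 / (n_points - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_evenness(pts: TraitPointSet) -> float:
    """Villeger FEve in [0, 1]; NaN for < 3 points or a fully degenerate
    (all-identical) cloud.  With equal weights the abundance terms cancel."""
    n = len(pts.points)
    if n < 3:
        return np.nan
    src, dst, d = mst_edges(pts.points)
    return _feve_from_edges(src, dst, d, pts.weights, n)


def adaptive_alpha(points: np.ndarray, factor: float = ADAPTIVE_ALPHA_FACTOR) -> float:
    """Window-local alpha: ``factor`` times the mean MST branch length."""
    _, _, d = mst_edges(points)
    if d.size == 0:
        return np.inf
    m = float(d.mean())
    return factor * m if m > 0 else np.inf


def functional_richness(
    pts: TraitPointSet,
    mode: str = "alpha_adaptive",
    alpha: float | None = None,
    min_points: int = 4,
) -> float:
    """Hull volume of the trait cloud (abundance-free); NaN below
    ``min_points``, 0 for degenerate (coplanar) clouds."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    p = pts.points
    if len(p) < min_points:
        return np.nan
    if mode == "convex":
        return convex_hull_volume(p)
    if mode == "alpha":
        if alpha is None:
            raise ValueError("fixed-alpha mode needs alpha")
        return alpha_shape_volume(p, alpha)
    return alpha_shape_volume(p, adaptive_alpha(p))


# ---------------------------------------------------------------------------
# map-level computation

@dataclass
class DiversityMap:
    fric: np.ndarray
    feve: np.ndarray
    n_points: np.ndarray
    radius_px: float
    mode: str
    alpha: float | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.fric) | np.isfinite(self.feve)


def map_functional_diversity(
    trait_stack: np.ndarray,
    mask: np.ndarray,
    kernel: CircularKernel,
    mode: str = "alpha_adaptive",
    alpha: float | None = None,
    min_points_fric: int = 4,
    min_points_feve: int = 3,
    min_weight_frac: float = 0.5,
    weighted_feve: bool = True,
    chunk: int = 256,
) -> DiversityMap:
    """Per-pixel FRic and FEve over the circular moving window.

    ``trait_stack`` is (3, rows, cols) rescaled trait values; ``mask`` marks
    valid center/neighbor pixels.  A center is reported only if its valid
    neighbors carry at least ``min_weight_frac`` of the total kernel weight;
    FRic additionally needs ``min_points_fric`` points, FEve
    ``min_points_feve``.  Kernel area fractions serve as FEve abundances
    when ``weighted_feve``; FRic is abundance-free by construction.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    traits = np.asarray(trait_stack, dtype=float)
    if traits.ndim != 3 or traits.shape[0] != 3:
        raise ValueError("trait_stack must be (3, rows, cols)")
    rows, cols = traits.shape[1:]
    if kernel.weights.shape[0] > rows or kernel.weights.shape[1] > cols:
        raise ValueError("kernel larger than raster")
    mask = np.asarray(mask, dtype=bool) & np.all(np.isfinite(traits), axis=0)

    dr, dc, w = kernel.offsets()
    n_off = len(dr)
    total_w = kernel.weight_sum

    # gather neighbor traits/validity by shifting, NaN-padded at borders
    nb_traits = np.full((n_off, 3, rows, cols), np.nan)
    nb_valid = np.zeros((n_off, rows, cols), dtype=bool)
    for k in range(n_off):
        r0, c0 = dr[k], dc[k]
        rs_src = slice(max(0, r0), rows + min(0, r0))
        cs_src = slice(max(0, c0), cols + min(0, c0))
        rs_dst = slice(max(0, -r0), rows + min(0, -r0))
        cs_dst = slice(max(0, -c0), cols + min(0, -c0))
        nb_valid[k, rs_dst, cs_dst] = mask[rs_src, cs_src]
        nb_traits[k, :, rs_dst, cs_dst] = traits[:, rs_src, cs_src]

    centers = np.flatnonzero(mask.ravel())
    nb_valid_f = nb_valid.reshape(n_off, -1)[:, centers].T          # (C, S)
    nb_traits_f = (
        nb_traits.reshape(n_off, 3, -1)[:, :, centers].transpose(2, 0, 1)
    )                                                               # (C, S, 3)
    w_valid = (nb_valid_f * w[None, :]).sum(axis=1)
    n_pts = nb_valid_f.sum(axis=1)

    enough_w = w_valid >= min_weight_frac * total_w
    fric_flat = np.full(rows * cols, np.nan)
    feve_flat = np.full(rows * cols, np.nan)
    n_flat = np.zeros(rows * cols)
    n_flat[centers] = n_pts

    weights_pts = np.broadcast_to(w[None, :], nb_valid_f.shape)

    for lo in range(0, len(centers), chunk):
        sel = slice(lo, lo + chunk)
        pv = nb_valid_f[sel]
        pt = np.where(pv[:, :, None], nb_traits_f[sel], 0.0)
        pw = weights_pts[sel]
        cidx = centers[sel]
        ok = enough_w[sel]
        # squared distances via the Gram matrix: avoids the (C, S, S, 3)
        # broadcast intermediate, which dominates on bandwidth-bound hosts
        sq = np.einsum("cik,cik->ci", pt, pt)
        gram = pt @ pt.transpose(0, 2, 1)
        d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * gram
        np.maximum(d2, 0.0, out=d2)
        dist = np.sqrt(d2)
        src, dst, d = _batch_prim(dist, pv)
        npts = pv.sum(axis=1)

        # FEve, vectorized across the chunk
        fin = np.isfinite(d)
        d0 = np.where(fin, d, 0.0)
        if weighted_feve:
            w_src = np.take_along_axis(pw, np.maximum(src, 0), axis=1)
            w_dst = np.take_along_axis(pw, np.maximum(dst, 0), axis=1)
            ew = np.where(fin, d0 / np.where(fin, w_src + w_dst, 1.0), 0.0)
        else:
            ew = d0
        ew_sum = ew.sum(axis=1)
        total_len = d0.sum(axis=1)
        n_edges = np.maximum(npts - 1, 1)
        thr = 1.0 / n_edges
        with np.errstate(invalid="ignore", divide="ignore"):
            pew = ew / ew_sum[:, None]
            contrib = np.where(fin, np.minimum(pew, thr[:, None]), 0.0).sum(axis=1)
            feve_c = (contrib - thr) / (1.0 - thr)
        good = ok & (npts >= min_points_feve) & (total_len > 0) & (ew_sum > 0)
        feve_flat[cidx[good]] = feve_c[good]

        # per-window mean MST branch length for the adaptive alpha
        mean_branch = np.where(
            fin.any(axis=1), d0.sum(axis=1) / np.maximum(fin.sum(axis=1), 1), np.inf
        )

        # FRic: the hull call itself stays per-window
        raw_pt = nb_traits_f[sel]
        for i in np.flatnonzero(ok & (npts >= min_points_fric)):
            p_i = raw_pt[i][pv[i]]
            if mode == "convex":
                fric_flat[cidx[i]] = convex_hull_volume(p_i)
            elif mode == "alpha":
                fric_flat[cidx[i]] = alpha_shape_volume(p_i, alpha)
            else:
                a_i = (
                    ADAPTIVE_ALPHA_FACTOR * mean_branch[i]
                    if np.isfinite(mean_branch[i]) and mean_branch[i] > 0
                    else np.inf
                )
                fric_flat[cidx[i]] = alpha_shape_volume(p_i, a_i)

    return DiversityMap(
        fric_flat.reshape(rows, cols),
        feve_flat.reshape(rows, cols),
        n_flat.reshape(rows, cols),
        kernel.radius_px,
        mode,
        alpha,
    )
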