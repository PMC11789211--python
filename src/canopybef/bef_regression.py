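"""Binned, weighted regression linking diversity to drought response.

Two analysis tracks:

* univariate: each diversity metric (rescaled to [0, 1]) is cut into 1000
  equal-range bins, drought responses are averaged per bin, bins with fewer
  than 1% of the maximum bin count are dropped, and linear / quadratic /
  logarithmic weighted least-squares fits (weights = pixel counts N) are
  compared by AIC;
* combined: pixels are stratified into 20 richness bins x 20 evenness bins
  x K subregions (8400 strata at K = 21); per-stratum mean responses are
  modelled by weighted least squares with terms entered in a fixed order so
  sequential (Type-I) sums of squares decompose total SS exactly.  SS
  percentages are increments of multiple r^2 x 100.  A conservative F-ratio
  (F2) tests each diversity term against its interaction with subregion,
  and a subregion correction (residuals from a region-only fit plus the
  weighted grand mean) yields region-adjusted response values for display.

Model formulas (R notation, term order preserved, weights = N):

    rst ~ logric + eve + eve^2 + REG + logric:REG + eve:REG + eve^2:REG
    rcv ~ logric + eve + eve^2 + REG + logric:REG + eve:REG + eve^2:REG
    rsl ~ ric + eve + REG + ric:REG + eve:REG

logric = log(ric + delta) with delta = half a bin width, since the lowest
richness bin center can be arbitrarily close to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_BIN_FRAC = 0.01

#: model term order per response kind (continuous terms before REG, then
#: diversity x region interactions, mirroring sequential fitting)
TERM_SETS = {
    "rst": ("logric", "eve", "eve2", "REG", "logric:REG", "eve:REG", "eve2:REG"),
    "rcv": ("logric", "eve", "eve2", "REG", "logric:REG", "eve:REG", "eve2:REG"),
    "rsl": ("ric", "eve", "REG", "ric:REG", "eve:REG"),
}


# ---------------------------------------------------------------------------
# binning

@dataclass
class BinnedSeries:
    """Equal-range binning of a [0, 1] metric with per-bin response means."""

    bin_id: np.ndarray            # per input value; -1 where invalid
    bin_edges: np.ndarray         # n_bins + 1 ascending edges on [0, 1]
    table: pd.DataFrame           # columns: bin, center, mean, n

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def equal_range_bins(
    values: np.ndarray, n_bins: int, response: np.ndarray | None = None
) -> BinnedSeries:
    """Cut values (rescaled to [0, 1]) into ``n_bins`` equal-range bins.

    Bin i covers [i/n, (i+1)/n), the last bin closed at 1.  The per-bin
    table holds the mean response (mean of the values themselves if no
    response is given) and the pixel count N.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    resp = v if response is None else np.asarray(response, dtype=float).ravel()
    ok = np.isfinite(v) & np.isfinite(resp) & (v >= 0.0) & (v <= 1.0)
    bins = np.full(v.shape, -1, dtype=np.int64)
    bins[ok] = np.minimum((v[ok] * n_bins).astype(np.int64), n_bins - 1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    n = np.bincount(bins[ok], minlength=n_bins)
    s = np.bincount(bins[ok], weights=resp[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    table = pd.DataFrame({
        "bin": np.arange(n_bins),
        "center": (edges[:-1] + edges[1:]) / 2.0,
        "mean": means,
        "n": n,
    })
    return BinnedSeries(bins.reshape(np.shape(values)), edges, table)


def filter_small_bins(
    series: BinnedSeries, min_frac: float = DEFAULT_MIN_BIN_FRAC
) -> BinnedSeries:
    """Drop bins with N < min_frac * max(N); the boundary count is kept."""
    t = series.table
    max_n = int(t["n"].max()) if len(t) else 0
    keep = t["n"] >= min_frac * max_n
    return BinnedSeries(series.bin_id, series.bin_edges, t[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# weighted univariate fits

@dataclass
class UnivariateFit:
    chosen: str
    params: dict
    reports: pd.DataFrame         # per-form aic / r2 / k
    log_offset: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        x = np.asarray(x, dtype=float)
        if self.chosen == "linear":
            return p["const"] + p["x"] * x
        if self.chosen == "quadratic":
            return p["const"] + p["x"] * x + p["x2"] * x**2
        return p["const"] + p["logx"] * np.log(x + self.log_offset)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    return beta, rss, rank


def _freq_weight_aic(rss: float, w: np.ndarray, k_params: int) -> float:
    """AIC from the Gaussian log-likelihood with frequency weights."""
    W = float(np.sum(w))
    sigma2 = max(rss / W, 1e-300)
    ll = -0.5 * W * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return 2.0 * (k_params + 1) - 2.0 * ll


def fit_univariate(
    series: BinnedSeries,
    forms: tuple[str, ...] = ("linear", "quadratic", "logarithmic"),
    log_offset: float | None = None,
) -> UnivariateFit:
    """Fit candidate forms by WLS (weights = N) and pick the minimum AIC.

    The logarithmic form uses log(x + delta) with delta defaulting to half
    a bin width; it is skipped with a warning if x + delta is not positive.
    """
    t = series.table.dropna(subset=["mean"])
    t = t[t["n"] > 0]
    if len(t) < 3:
        raise ValueError("need at least 3 surviving bins")
    x = t["center"].to_numpy()
    y = t["mean"].to_numpy()
    w = t["n"].to_numpy(dtype=float)
    if log_offset is None:
        log_offset = 0.5 * float(np.diff(series.bin_edges[:2])[0])
    tss = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    rows, fits = [], {}
    for form in forms:
        if form == "linear":
            X = np.column_stack([np.ones_like(x), x])
            names = ["const", "x"]
        elif form == "quadratic":
            X = np.column_stack([np.ones_like(x), x, x**2])
            names = ["const", "x", "x2"]
        elif form == "logarithmic":
            if np.any(x + log_offset <= 0):
                import warnings

                warnings.warn("non-positive predictor; skipping log form")
                continue
            X = np.column_stack([np.ones_like(x), np.log(x + log_offset)])
            names = ["const", "logx"]
        else:
            raise ValueError(f"unknown form {form!r}")
        beta, rss, _ = _wls(X, y, w)
        aic = _freq_weight_aic(rss, w, len(names))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        rows.append({"form": form, "aic": aic, "r2": r2, "k": len(names)})
        fits[form] = dict(zip(names, beta))
    if not rows:
        raise ValueError("no candidate form could be fitted")
    reports = pd.DataFrame(rows).set_index("form")
    chosen = str(reports["aic"].idxmin())
    return UnivariateFit(chosen, fits[chosen], reports, log_offset)


# ---------------------------------------------------------------------------
# stratification

@dataclass
class StratifiedTable:
    """(ric_bin x eve_bin x region) strata with mean responses and counts."""

    data: pd.DataFrame
    n_bins: int
    regions: np.ndarray

    @property
    def n_strata(self) -> int:
        return len(self.data)

    def nonempty(self) -> pd.DataFrame:
        return self.data[self.data["N"] > 0]


def stratified_table(
    ric01: np.ndarray,
    eve01: np.ndarray,
    region_map: np.ndarray,
    response_maps: dict[str, np.ndarray],
    valid: np.ndarray | None = None,
    n_bins: int = 20,
) -> StratifiedTable:
    """Aggregate pixels into the full bin x bin x region product.

    Empty strata are retained as rows with N = 0 (NaN means) for
    accounting; fitting excludes them.
    """
    shapes = {np.shape(ric01), np.shape(eve01), np.shape(region_map)}
    shapes |= {np.shape(v) for v in response_maps.values()}
    if len(shapes) > 1:
        raise ValueError("all maps must share one grid")
    regions = np.unique(np.asarray(region_map)[np.asarray(region_map) > 0])
    if regions.size == 0:
        raise ValueError("region map has no positive labels")
    r = np.asarray(ric01, dtype=float).ravel()
    e = np.asarray(eve01, dtype=float).ravel()
    g = np.asarray(region_map).ravel()
    ok = np.isfinite(r) & np.isfinite(e) & (g > 0)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool).ravel()
    for v in response_maps.values():
        ok &= np.isfinite(np.asarray(v, dtype=float).ravel())
    rb = np.minimum((np.nan_to_num(np.clip(r, 0, 1)) * n_bins).astype(int), n_bins - 1)
    eb = np.minimum((np.nan_to_num(np.clip(e, 0, 1)) * n_bins).astype(int), n_bins - 1)
    df = pd.DataFrame({"ric_bin": rb[ok], "eve_bin": eb[ok], "region": g[ok]})
    for name, v in response_maps.items():
        df[name] = np.asarray(v, dtype=float).ravel()[ok]
    grouped = df.groupby(["ric_bin", "eve_bin", "region"], sort=True)
    agg = grouped.mean()
    agg["N"] = grouped.size()
    full_index = pd.MultiIndex.from_product(
        [np.arange(n_bins), np.arange(n_bins), regions],
        names=["ric_bin", "eve_bin", "region"],
    )
    agg = agg.reindex(full_index)
    agg["N"] = agg["N"].fillna(0).astype(int)
    agg = agg.reset_index()
    centers = (np.arange(n_bins) + 0.5) / n_bins
    agg["ric"] = centers[agg["ric_bin"]]
    agg["eve"] = centers[agg["eve_bin"]]
    return StratifiedTable(agg, n_bins, regions)


# ---------------------------------------------------------------------------
# sequential (Type-I) weighted ANOVA

@dataclass
class AnovaTable:
    response: str
    table: pd.DataFrame            # term, df, ss, ms, F, p, r2_inc [, F2 ...]
    total_ss: float
    resid_ss: float
    resid_df: int
    coefficients: dict = field(default_factory=dict)
    coef_se: dict = field(default_factory=dict)
    rank_deficient: list = field(default_factory=list)

    @property
    def model_r2(self) -> float:
        return 1.0 - self.resid_ss / self.total_ss if self.total_ss > 0 else 0.0

    @property
    def resid_ms(self) -> float:
        return self.resid_ss / self.resid_df if self.resid_df > 0 else np.nan


def _design_blocks(df: pd.DataFrame, terms, log_offset: float):
    """Ordered (term, column matrix, column names) triples plus intercept."""
    regions = np.sort(df["region"].unique())
    reg_dummies = np.column_stack(
        [(df["region"] == r).to_numpy(float) for r in regions[1:]]
    ) if len(regions) > 1 else np.empty((len(df), 0))
    reg_names = [f"REG[{r}]" for r in regions[1:]]
    cont = {
        "ric": df["ric"].to_numpy(float),
        "eve": df["eve"].to_numpy(float),
        "eve2": df["eve"].to_numpy(float) ** 2,
        "logric": np.log(df["ric"].to_numpy(float) + log_offset),
    }
    blocks = []
    for term in terms:
        if term == "REG":
            blocks.append((term, reg_dummies, reg_names))
        elif ":" in term:
            base, _ = term.split(":")
            x = cont[base]
            cols = reg_dummies * x[:, None]
            blocks.append((term, cols, [f"{base}:{n}" for n in reg_names]))
        else:
            blocks.append((term, cont[term][:, None], [term]))
    return blocks


def fit_combined(
    table: StratifiedTable,
    response: str,
    terms: tuple[str, ...] | None = None,
    log_offset: float | None = None,
) -> AnovaTable:
    """Weighted sequential-SS fit of one response on the stratified table.

    Terms enter in the listed order; each term's SS is the drop in weighted
    residual SS when its columns join the design (Type-I).  F tests use the
    residual mean square.  Rank-deficient terms get the SS of their
    estimable subspace and are flagged.
    """
    if terms is None:
        key = response if response in TERM_SETS else "rst"
        terms = TERM_SETS[key]
    df = table.nonempty().dropna(subset=[response])
    if len(df) < 2:
        raise ValueError("need at least 2 nonempty strata")
    if log_offset is None:
        log_offset = 0.5 / table.n_bins
    y = df[response].to_numpy(float)
    w = df["N"].to_numpy(float)
    blocks = _design_blocks(df, terms, log_offset)

    X = np.ones((len(df), 1))
    names = ["const"]
    _, rss_prev, rank_prev = _wls(X, y, w)
    total_ss = rss_prev
    rows, flagged = [], []
    for term, cols, cnames in blocks:
        X = np.column_stack([X, cols])
        names += cnames
        _, rss, rank = _wls(X, y, w)
        df_term = rank - rank_prev
        if df_term < cols.shape[1]:
            flagged.append(term)
        ss = max(rss_prev - rss, 0.0)
        rows.append({"term": term, "df": int(df_term), "ss": ss})
        rss_prev, rank_prev = rss, rank
    beta, resid_ss, rank_full = _wls(X, y, w)
    resid_df = len(df) - rank_full
    resid_ms = resid_ss / resid_df if resid_df > 0 else np.nan
    xtwx = (X * w[:, None]).T @ X
    cov = resid_ms * np.linalg.pinv(xtwx)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    for r in rows:
        r["ms"] = r["ss"] / r["df"] if r["df"] > 0 else np.nan
        r["F"] = r["ms"] / resid_ms if resid_df > 0 and resid_ms > 0 else np.nan
        r["p"] = (
            float(stats.f.sf(r["F"], r["df"], resid_df))
            if np.isfinite(r.get("F", np.nan)) and r["df"] > 0
            else np.nan
        )
        r["r2_inc"] = r["ss"] / total_ss if total_ss > 0 else np.nan
    return AnovaTable(
        response=response,
        table=pd.DataFrame(rows),
        total_ss=total_ss,
        resid_ss=resid_ss,
        resid_df=int(resid_df),
        coefficients=dict(zip(names, beta)),
        coef_se=dict(zip(names, se)),
        rank_deficient=flagged,
    )


def conservative_f(anova: AnovaTable) -> AnovaTable:
    """Add F2 = MS(term) / MS(term x REG) for each diversity main effect.

    Testing a diversity effect against its interaction with subregion asks
    whether the average effect exceeds its between-region variability — the
    fixed-model analogue of treating the interaction as a random term.
    """
    t = anova.table.set_index("term")
    f2, df2, p2 = {}, {}, {}
    for term in t.index:
        inter = f"{term}:REG"
        if ":" in term or term == "REG":
            continue
        if inter not in t.index:
            raise KeyError(f"missing interaction term {inter} for {term}")
        ms_i = t.loc[inter, "ms"]
        f2[term] = float(t.loc[term, "ms"] / ms_i) if ms_i > 0 else np.nan
        df2[term] = (int(t.loc[term, "df"]), int(t.loc[inter, "df"]))
        p2[term] = (
            float(stats.f.sf(f2[term], *df2[term]))
            if np.isfinite(f2[term])
            else np.nan
        )
    out = anova.table.copy()
    out["F2"] = out["term"].map(f2)
    out["df2"] = out["term"].map(df2)
    out["p2"] = out["term"].map(p2)
    return AnovaTable(
        anova.response, out, anova.total_ss, anova.resid_ss, anova.resid_df,
        anova.coefficients, anova.coef_se, anova.rank_deficient,
    )


def region_correct(table: StratifiedTable, response: str) -> pd.Series:
    """Region-adjusted response: residual from a weighted region-only fit
    plus the weighted grand mean (aligned to the nonempty strata)."""
    df = table.nonempty().dropna(subset=[response])
    y = df[response].to_numpy(float)
    w = df["N"].to_numpy(float)
    regions = np.sort(df["region"].unique())
    X = np.column_stack(
        [np.ones(len(df))]
        + [(df["region"] == r).to_numpy(float) for r in regions[1:]]
    )
    beta, _, _ = _wls(X, y, w)
    resid = y - X @ beta
    grand = float(np.average(y, weights=w))
    return pd.Series(resid + grand, index=df.index, name=f"{response}_corrected")
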