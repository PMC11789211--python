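"""Binning, weighted fits, sequential SS, and the subregion machinery."""

import numpy as np
import pandas as pd
import pytest

from canopybef import (
    conservative_f,
    equal_range_bins,
    filter_small_bins,
    fit_combined,
    fit_univariate,
    region_correct,
    stratified_table,
)
from canopybef.bef_regression import AnovaTable, _wls


class TestEqualRangeBins:
    def test_edge_conventions(self):
        s = equal_range_bins(np.array([0.25, 0.75, 1.0]), 2)
        assert list(s.bin_id) == [0, 1, 1]

    def test_uniform_values_spread_evenly(self):
        rng = np.random.default_rng(0)
        v = rng.random(100_000)
        s = equal_range_bins(v, 1000)
        n = s.table["n"].to_numpy()
        # binomial sampling error around 100 per bin
        assert np.all(np.abs(n - 100) < 5 * np.sqrt(100))

    def test_single_bin_occupied(self):
        s = equal_range_bins(np.full(10, 0.42), 1000)
        assert (s.table["n"] > 0).sum() == 1

    def test_response_means(self):
        v = np.array([0.1, 0.15, 0.9])
        y = np.array([1.0, 3.0, 10.0])
        s = equal_range_bins(v, 2, y)
        assert s.table.loc[0, "mean"] == pytest.approx(2.0)
        assert s.table.loc[1, "mean"] == pytest.approx(10.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            equal_range_bins(np.array([]), 10)


class TestFilterSmallBins:
    def _series(self, counts):
        v = np.concatenate([
            np.full(c, (i + 0.5) / len(counts)) for i, c in enumerate(counts)
        ])
        return equal_range_bins(v, len(counts))

    def test_below_one_percent_dropped(self):
        s = self._series([1000, 9, 500])
        out = filter_small_bins(s, 0.01)
        assert list(out.table["bin"]) == [0, 2]

    def test_boundary_count_kept(self):
        s = self._series([1000, 10, 500])
        out = filter_small_bins(s, 0.01)
        assert list(out.table["bin"]) == [0, 1, 2]

    def test_zero_fraction_is_identity(self):
        s = self._series([50, 2, 7])
        out = filter_small_bins(s, 0.0)
        assert len(out.table) == len(s.table)


class TestUnivariateFit:
    def _series_from_xy(self, x, y, w=None):
        n_bins = len(x)
        table = pd.DataFrame({
            "bin": np.arange(n_bins),
            "center": x,
            "mean": y,
            "n": np.ones(n_bins) if w is None else w,
        })
        from canopybef.bef_regression import BinnedSeries

        return BinnedSeries(np.arange(n_bins), np.linspace(0, 1, n_bins + 1), table)

    def test_exact_linear_selected(self):
        x = np.linspace(0.05, 0.95, 40)
        fit = fit_univariate(self._series_from_xy(x, 2 * x + 1))
        assert fit.chosen == "linear"
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.reports.loc["linear", "r2"] == pytest.approx(1.0)

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0.05, 0.95, 60)
        y = 1.2 - 0.8 * x + rng.normal(0, 0.05, 60)
        fit_w = fit_univariate(
            self._series_from_xy(x, y, np.full(60, 7.0)), forms=("linear",)
        )
        coef = np.polyfit(x, y, 1)
        assert fit_w.params["x"] == pytest.approx(coef[0], abs=1e-9)
        assert fit_w.params["const"] == pytest.approx(coef[1], abs=1e-9)

    def test_log_relationship_recovered_across_seeds(self):
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = np.linspace(0.001, 1.0, 800)
            y = 0.1 + 0.05 * np.log(x) + rng.normal(0, 0.01, x.size)
            fit = fit_univariate(self._series_from_xy(x, y))
            wins += fit.chosen == "logarithmic"
        assert wins > n_seeds / 2

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            fit_univariate(self._series_from_xy(np.array([0.1, 0.9]), np.array([1.0, 2.0])))


# ---------------------------------------------------------------------------
# stratification

def _random_maps(rng, shape=(40, 40), k=21):
    ric = rng.random(shape)
    eve = rng.random(shape)
    region = rng.integers(1, k + 1, size=shape)
    return ric, eve, region


class TestStratifiedTable:
    def test_full_product_20x20x21(self):
        rng = np.random.default_rng(2)
        ric, eve, region = _random_maps(rng)
        resp = {"rst": rng.normal(size=ric.shape)}
        table = stratified_table(ric, eve, region, resp, n_bins=20)
        assert table.n_strata == 8400

    def test_small_product(self):
        rng = np.random.default_rng(3)
        ric, eve, region = _random_maps(rng, k=1)
        table = stratified_table(ric, eve, region, {"rst": ric}, n_bins=2)
        assert table.n_strata == 4

    def test_counts_conserve_pixels(self):
        rng = np.random.default_rng(4)
        ric, eve, region = _random_maps(rng, shape=(30, 30), k=5)
        table = stratified_table(ric, eve, region, {"rst": ric}, n_bins=10)
        assert table.data["N"].sum() == 900

    def test_single_pixel_stratum_mean_identity(self):
        ric = np.array([[0.025]])
        eve = np.array([[0.975]])
        region = np.array([[1]])
        table = stratified_table(ric, eve, region, {"rst": np.array([[0.37]])}, n_bins=20)
        row = table.nonempty().iloc[0]
        assert row["rst"] == pytest.approx(0.37)
        assert row["N"] == 1

    def test_no_regions_raises(self):
        with pytest.raises(ValueError):
            stratified_table(
                np.array([[0.5]]), np.array([[0.5]]), np.array([[0]]),
                {"rst": np.array([[1.0]])},
            )


# ---------------------------------------------------------------------------
# sequential weighted ANOVA

def _synthetic_table(rng, k=6, n_bins=10, beta_ric=0.2, beta_eve=-0.1,
                     noise=0.01, region_sd=0.05, response="rsl"):
    centers = (np.arange(n_bins) + 0.5) / n_bins
    ric, eve, reg = np.meshgrid(centers, centers, np.arange(1, k + 1), indexing="ij")
    ric, eve, reg = ric.ravel(), eve.ravel(), reg.ravel()
    offsets = rng.normal(0, region_sd, k)
    y = beta_ric * ric + beta_eve * eve + offsets[reg - 1] + rng.normal(0, noise, ric.size)
    df = pd.DataFrame({
        "ric_bin": (ric * n_bins - 0.5).astype(int),
        "eve_bin": (eve * n_bins - 0.5).astype(int),
        "region": reg,
        response: y,
        "N": rng.integers(1, 50, ric.size),
        "ric": ric,
        "eve": eve,
    })
    from canopybef.bef_regression import StratifiedTable

    return StratifiedTable(df, n_bins, np.arange(1, k + 1))


class TestFitCombined:
    def test_balanced_design_order_independent(self):
        rng = np.random.default_rng(5)
        table = _synthetic_table(rng, noise=0.02)
        table.data["N"] = 1  # balanced and equal-weighted: orthogonal design
        a1 = fit_combined(table, "rsl", terms=("ric", "eve", "REG"))
        a2 = fit_combined(table, "rsl", terms=("eve", "ric", "REG"))
        t1 = a1.table.set_index("term")
        t2 = a2.table.set_index("term")
        for term in ("ric", "eve", "REG"):
            assert t1.loc[term, "ss"] == pytest.approx(t2.loc[term, "ss"], rel=1e-9)
        assert a1.table["ss"].sum() == pytest.approx(a2.table["ss"].sum(), rel=1e-12)

    def test_ss_decomposition_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            table = _synthetic_table(rng)
            a = fit_combined(table, "rsl")
            total = a.table["ss"].sum() + a.resid_ss
            assert total == pytest.approx(a.total_ss, rel=1e-8)
            assert a.table["r2_inc"].sum() == pytest.approx(a.model_r2, rel=1e-8)

    def test_permuted_order_conserves_total(self):
        rng = np.random.default_rng(7)
        table = _synthetic_table(rng)
        a1 = fit_combined(table, "rsl", terms=("ric", "eve", "REG", "ric:REG", "eve:REG"))
        a2 = fit_combined(table, "rsl", terms=("REG", "eve", "ric", "eve:REG", "ric:REG"))
        assert a1.table["ss"].sum() == pytest.approx(a2.table["ss"].sum(), rel=1e-9)

    def test_known_slope_recovered_within_2se(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            beta = 0.2
            table = _synthetic_table(rng, beta_ric=beta)
            a = fit_combined(table, "rsl")
            se = a.coef_se["ric"]
            hits += abs(a.coefficients["ric"] - beta) <= 2 * se
        assert hits >= 9

    def test_pure_noise_type_one_error_calibrated(self):
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            table = _synthetic_table(
                rng, beta_ric=0.0, beta_eve=0.0, region_sd=0.0, noise=1.0
            )
            table.data["N"] = 1  # homoscedastic noise: unit frequency weights
            a = fit_combined(table, "rsl", terms=("ric", "eve", "REG"))
            p = a.table.set_index("term").loc["ric", "p"]
            rejections += p < 0.05
        rate = rejections / n_seeds
        assert 0.01 < rate < 0.10

    def test_weighted_bin_fit_equals_pixel_fit(self):
        # aggregating pixels with stratum-constant predictors and weighting
        # by N must reproduce the pixel-level fit exactly
        rng = np.random.default_rng(8)
        n_strata, reps = 30, 5
        x = rng.random(n_strata)
        pix_y = 0.5 + 0.3 * x[None, :] + rng.normal(0, 0.1, (reps, n_strata))
        X_strat = np.column_stack([np.ones(n_strata), x])
        beta_binned, _, _ = _wls(
            X_strat, pix_y.mean(axis=0), np.full(n_strata, float(reps))
        )
        X_pix = np.column_stack([np.ones(reps * n_strata), np.tile(x, reps)])
        beta_pix, _, _ = _wls(X_pix, pix_y.ravel(), np.ones(reps * n_strata))
        assert np.allclose(beta_binned, beta_pix, atol=1e-9)


class TestConservativeF:
    def test_f2_relationships(self):
        rng = np.random.default_rng(9)
        table = _synthetic_table(rng, region_sd=0.08)
        a = conservative_f(fit_combined(table, "rsl"))
        t = a.table.set_index("term")
        for term in ("ric", "eve"):
            ms_int = t.loc[f"{term}:REG", "ms"]
            expected = t.loc[term, "ms"] / ms_int
            assert t.loc[term, "F2"] == pytest.approx(expected)
            # F2 = F rescaled by the ratio of error mean squares
            assert t.loc[term, "F2"] == pytest.approx(
                t.loc[term, "F"] * a.resid_ms / ms_int
            )

    def test_region_varying_slopes_shrink_f2(self):
        # when the diversity slope truly varies between regions, the
        # interaction MS exceeds the residual MS, so F2 < F on average
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            k, n_bins = 6, 10
            centers = (np.arange(n_bins) + 0.5) / n_bins
            ric, eve, reg = np.meshgrid(
                centers, centers, np.arange(1, k + 1), indexing="ij"
            )
            ric, eve, reg = ric.ravel(), eve.ravel(), reg.ravel()
            slopes = 0.2 + rng.normal(0, 0.1, k)
            y = slopes[reg - 1] * ric + rng.normal(0, 0.02, ric.size)
            df = pd.DataFrame({
                "ric_bin": 0, "eve_bin": 0, "region": reg,
                "rsl": y, "N": 1, "ric": ric, "eve": eve,
            })
            from canopybef.bef_regression import StratifiedTable

            table = StratifiedTable(df, n_bins, np.arange(1, k + 1))
            a = conservative_f(fit_combined(table, "rsl"))
            t = a.table.set_index("term")
            wins += t.loc["ric", "F2"] < t.loc["ric", "F"]
        assert wins > 0.8 * n_seeds

    def test_missing_interaction_raises(self):
        rng = np.random.default_rng(10)
        table = _synthetic_table(rng)
        a = fit_combined(table, "rsl", terms=("ric", "eve", "REG", "eve:REG"))
        with pytest.raises(KeyError):
            conservative_f(a)


class TestRegionCorrect:
    def test_single_region_identity(self):
        rng = np.random.default_rng(11)
        table = _synthetic_table(rng, k=1)
        out = region_correct(table, "rsl")
        assert np.allclose(out.to_numpy(), table.data["rsl"].to_numpy())

    def test_corrected_region_means_equalized(self):
        rng = np.random.default_rng(12)
        table = _synthetic_table(rng, region_sd=0.3, noise=0.0)
        corrected = region_correct(table, "rsl")
        df = table.nonempty().assign(corr=corrected)
        means = [
            np.average(g["corr"], weights=g["N"])
            for _, g in df.groupby("region")
        ]
        assert np.std(means) < 1e-9

    def test_weighted_mean_preserved(self):
        rng = np.random.default_rng(13)
        table = _synthetic_table(rng)
        corrected = region_correct(table, "rsl")
        df = table.nonempty()
        grand = np.average(df["rsl"], weights=df["N"])
        got = np.average(corrected, weights=df["N"])
        assert got == pytest.approx(grand, abs=1e-10)


def test_anova_table_model_r2_definition():
    a = AnovaTable(
        "rst",
        pd.DataFrame({"term": ["x"], "df": [1], "ss": [3.0]}),
        total_ss=4.0, resid_ss=1.0, resid_df=10,
    )
    assert a.model_r2 == pytest.approx(0.75)
    assert a.resid_ms == pytest.approx(0.1)
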