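import math

import numpy as np
import pandas as pd
import pytest

from heatlag.fixed_effects_model import (
    FitResult,
    build_design,
    compute_aic,
    compute_lsm,
    extend_with_factor,
    fit_ols,
)
from heatlag.records_io import ValidationError


def _frame(**cols):
    return pd.DataFrame(cols)


def _random_table(rng, n, with_thi=True):
    frame = pd.DataFrame({
        "herd": rng.choice([f"H{i}" for i in range(4)], n),
        "year": rng.choice([2010, 2011, 2012], n),
        "month": rng.integers(1, 13, n),
        "age_group": rng.integers(1, 4, n),
        "dim_class": rng.integers(6, 30, n),
    })
    if with_thi:
        frame["thi_class"] = rng.integers(40, 50, n)
    return frame


class TestBuildDesign:
    def test_one_factor_two_levels(self):
        frame = _frame(f=["a", "a", "b", "b"])
        d = build_design(frame, factors=["f"])
        assert d.X.shape == (4, 2)        # intercept + 1 indicator
        assert d.rank == 2

    def test_thi_toggle_adds_classes_minus_one_columns(self):
        rng = np.random.default_rng(0)
        frame = _random_table(rng, 200)
        basic = build_design(frame, include_thi=False)
        full = build_design(frame, include_thi=True)
        n_classes = frame["thi_class"].nunique()
        assert full.X.shape[1] - basic.X.shape[1] == n_classes - 1

    def test_confounded_factor_dropped_first_seen_kept(self):
        # b is a relabelling of a: its indicator columns are aliased
        frame = _frame(a=["x", "x", "y", "y"], b=["p", "p", "q", "q"])
        d = build_design(frame, factors=["a", "b"])
        assert [c for c, k in zip(d.columns, d.kept) if not k] == [("b", "q")]
        dense = d.X.toarray()
        assert d.rank == np.linalg.matrix_rank(dense)

    def test_single_level_factor_absorbed_with_warning(self, caplog):
        frame = _frame(a=["x", "x", "y", "y"], b=["only"] * 4)
        with caplog.at_level("WARNING"):
            d = build_design(frame, factors=["a", "b"])
        assert "single level" in caplog.text
        assert d.X.shape[1] == 2

    def test_null_labels_raise(self):
        frame = _frame(a=["x", None, "y", "y"])
        with pytest.raises(ValidationError, match="null"):
            build_design(frame, factors=["a"])

    def test_extend_path_equals_direct_build(self):
        rng = np.random.default_rng(3)
        frame = _random_table(rng, 300)
        y = rng.normal(size=300)
        direct = build_design(frame, include_thi=True)
        extended = extend_with_factor(
            build_design(frame, include_thi=False),
            frame["thi_class"].to_numpy())
        assert direct.columns == extended.columns
        np.testing.assert_array_equal(direct.kept, extended.kept)
        fa, fb = fit_ols(direct, y), fit_ols(extended, y)
        assert fa.aic == pytest.approx(fb.aic, abs=1e-8)
        np.testing.assert_allclose(fa.beta_kept, fb.beta_kept, atol=1e-9)


class TestFitOls:
    def test_saturated_balanced_means(self):
        frame = _frame(f=["a", "a", "b", "b"])
        d = build_design(frame, factors=["f"])
        fit = fit_ols(d, np.array([1.0, 1.0, 3.0, 3.0]))
        coefs = fit.coefficients
        assert coefs["(intercept)"] == pytest.approx(1.0)
        assert coefs["f=b"] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.degenerate

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_pseudoinverse_and_statsmodels(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        n = 150
        frame = _random_table(rng, n)
        y = rng.normal(size=n)
        d = build_design(frame, include_thi=True)
        fit = fit_ols(d, y)
        dense = d.X.toarray()
        beta_pinv = np.linalg.pinv(dense) @ y
        fitted_pinv = dense @ beta_pinv
        fitted = d.Xk @ fit.beta_kept
        np.testing.assert_allclose(fitted, fitted_pinv, atol=1e-8)
        assert fit.rss == pytest.approx(float(((y - fitted_pinv) ** 2).sum()),
                                        abs=1e-8)
        res = sm.OLS(y, dense).fit()
        np.testing.assert_allclose(fitted, res.fittedvalues, atol=1e-8)

    def test_constant_response_is_degenerate(self):
        frame = _frame(f=["a", "b", "a", "b"])
        d = build_design(frame, factors=["f"])
        fit = fit_ols(d, np.full(4, 7.0))
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.degenerate and fit.aic == -math.inf

    def test_unidentifiable_raises(self):
        frame = _frame(f=["a", "b"])
        d = build_design(frame, factors=["f"])
        with pytest.raises(ValidationError, match="unidentifiable"):
            fit_ols(d, np.array([1.0, 2.0]))

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(9)
        frame = _random_table(rng, 120)
        y = rng.normal(size=120)
        d = build_design(frame)
        fit = fit_ols(d, y)
        resid = y - d.Xk @ fit.beta_kept
        np.testing.assert_allclose(d.Xk.T @ resid, 0.0, atol=1e-8)


class TestAic:
    def test_closed_form(self):
        fit = FitResult(design=None, beta_kept=None, rss=100.0, n=100, rank=2,
                        sigma2_hat=1.0, aic=np.nan)
        assert compute_aic(fit) == pytest.approx(100 * math.log(2 * math.pi)
                                                 + 100 + 6)

    def test_delta_is_twice_delta_rank_at_equal_rss(self):
        a = FitResult(design=None, beta_kept=None, rss=50.0, n=200, rank=10,
                      sigma2_hat=0.25, aic=np.nan)
        b = FitResult(design=None, beta_kept=None, rss=50.0, n=200, rank=11,
                      sigma2_hat=0.25, aic=np.nan)
        assert compute_aic(b) - compute_aic(a) == pytest.approx(2.0)

    def test_difference_invariant_to_additive_convention(self):
        # AIC differences reduce to n log(rss ratio) + 2 delta-rank
        rng = np.random.default_rng(5)
        frame = _random_table(rng, 100)
        y = rng.normal(size=100)
        fb = fit_ols(build_design(frame, include_thi=False), y)
        ff = fit_ols(build_design(frame, include_thi=True), y)

        def reduced(f):   # convention without the n log(2 pi) + n + 2 terms
            return f.n * math.log(f.rss / f.n) + 2.0 * f.rank

        assert ff.aic - fb.aic == pytest.approx(reduced(ff) - reduced(fb),
                                                abs=1e-8)

    def test_degenerate_fit_flagged(self):
        fit = FitResult(design=None, beta_kept=None, rss=0.0, n=10, rank=2,
                        sigma2_hat=0.0, aic=np.nan, degenerate=True)
        assert compute_aic(fit) == -math.inf

    def test_noise_factor_inflates_aic_in_expectation(self):
        # an unrelated many-level factor should raise AIC on average
        rng = np.random.default_rng(11)
        deltas = []
        for _ in range(200):
            n = 120
            frame = pd.DataFrame({"herd": rng.choice(["a", "b"], n),
                                  "thi_class": rng.integers(0, 25, n)})
            y = rng.normal(size=n)
            fb = fit_ols(build_design(frame, factors=["herd"]), y)
            ff = fit_ols(extend_with_factor(
                build_design(frame, factors=["herd"]),
                frame["thi_class"].to_numpy()), y)
            deltas.append(ff.aic - fb.aic)
        assert np.mean(deltas) > 0


class TestLsm:
    def test_single_factor_lsm_is_class_mean(self):
        frame = _frame(thi_class=[60, 60, 61, 61, 61])
        d = build_design(frame, factors=["thi_class"])
        fit = fit_ols(d, np.array([1.0, 3.0, 5.0, 6.0, 10.0]))
        lsm = compute_lsm(fit)
        np.testing.assert_allclose(lsm["lsm"], [2.0, 7.0])
        np.testing.assert_array_equal(lsm["count"], [2, 3])

    def test_balanced_two_way_equals_group_means(self):
        rng = np.random.default_rng(2)
        thi = np.repeat([70, 71, 72], 4)
        herd = np.tile(["a", "b"], 6)
        y = rng.normal(size=12)
        frame = _frame(thi_class=thi, herd=herd)
        fit = fit_ols(build_design(frame, factors=["herd", "thi_class"]), y)
        lsm = compute_lsm(fit)
        raw = pd.Series(y).groupby(thi).mean()
        np.testing.assert_allclose(lsm["lsm"], raw.to_numpy(), atol=1e-10)

    def test_unbalanced_equal_weight_cell_mean_average(self):
        # additive cell means: herd a: 10, 12; herd b: 14, 16 (thi 60, 61);
        # unbalanced counts, so record-weighted means would differ
        frame = _frame(
            thi_class=[60, 60, 60, 61, 60, 61, 61, 61],
            herd=["a", "a", "a", "a", "b", "b", "b", "b"],
        )
        y = np.array([10.0, 10.0, 10.0, 12.0, 14.0, 16.0, 16.0, 16.0])
        fit = fit_ols(build_design(frame, factors=["herd", "thi_class"]), y)
        lsm = compute_lsm(fit)
        np.testing.assert_allclose(lsm["lsm"], [12.0, 14.0], atol=1e-10)
        record_weighted = pd.Series(y).groupby(frame["thi_class"]).mean()
        assert abs(record_weighted.loc[60] - 12.0) > 0.4

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(4)
        frame = _random_table(rng, 80)
        fit = fit_ols(build_design(frame), rng.normal(size=80))
        assert compute_lsm(fit)["count"].sum() == 80

    def test_se_matches_statsmodels_contrast(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        frame = _frame(thi_class=rng.integers(60, 63, 40),
                       herd=rng.choice(["a", "b", "c"], 40))
        y = rng.normal(size=40)
        d = build_design(frame, factors=["herd", "thi_class"])
        fit = fit_ols(d, y)
        lsm = compute_lsm(fit)
        res = sm.OLS(y, d.X.toarray()).fit()
        levels = d.factor_levels["thi_class"]
        for j, lv in enumerate(levels):
            c = np.zeros(d.X.shape[1])
            c[0] = 1.0
            for i, (f, flv) in enumerate(d.columns):
                if f == "herd":
                    c[i] = 1.0 / 3.0
                if f == "thi_class" and flv == lv:
                    c[i] = 1.0
            expected_se = float(np.asarray(res.t_test(c).sd).ravel()[0])
            assert lsm["se"].iloc[j] == pytest.approx(expected_se, rel=1e-8)

    def test_absent_factor_raises(self):
        frame = _frame(herd=["a", "a", "b", "b"])
        fit = fit_ols(build_design(frame, factors=["herd"]),
                      np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValidationError):
            compute_lsm(fit, factor="thi_class")
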