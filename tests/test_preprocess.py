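"""Preparation chain: LOQ filter, transforms, imputation, adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbmix import (
    GeneratorConfig,
    adjust_covariates,
    correct_outliers,
    filter_loq,
    generate_panel,
    impute_censored,
    impute_missing,
    log_transform,
    preprocess_pipeline,
    standardize,
)
from hbmix.network import partial_correlations

from conftest import make_panel


class TestFilterLoq:
    @pytest.mark.parametrize("n_cens, expect_excluded", [(41, True), (40, False)])
    def test_cutoff_is_strict(self, n_cens, expect_excluded):
        # "more than 40%" excluded: 41/100 goes, exactly 40/100 stays
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(100, 2))
        cens = np.zeros((100, 2), bool)
        cens[:n_cens, 0] = True
        panel = make_panel(vals, loq=0.5, censored=cens)
        kept, report = filter_loq(panel)
        assert report.loc["B01", "excluded"] == expect_excluded
        assert ("B01" in kept.biomarkers) != expect_excluded
        assert "B02" in kept.biomarkers

    def test_nothing_excluded_without_censoring(self):
        panel = make_panel(np.random.default_rng(1).lognormal(size=(50, 4)))
        kept, report = filter_loq(panel)
        assert not report["excluded"].any()
        assert kept.biomarkers == panel.biomarkers

    def test_all_missing_biomarker_reported_no_data(self):
        vals = np.ones((20, 2))
        miss = np.zeros((20, 2), bool)
        miss[:, 1] = True
        vals[:, 1] = np.nan
        panel = make_panel(vals, missing=miss)
        kept, report = filter_loq(panel)
        assert report.loc["B02", "reason"] == "no data"
        assert kept.biomarkers == ["B01"]

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(size=(60, 5))
        cens = rng.random((60, 5)) < 0.45
        panel = make_panel(vals, loq=1.0, censored=cens)
        _, rep = filter_loq(panel)
        shuffled = panel.copy()
        perm_rows = rng.permutation(60)
        perm_cols = rng.permutation(5)
        cols = [panel.biomarkers[j] for j in perm_cols]
        shuffled.values = panel.values.iloc[perm_rows][cols]
        shuffled.censored = panel.censored.iloc[perm_rows][cols]
        shuffled.missing = panel.missing.iloc[perm_rows][cols]
        shuffled.loq = panel.loq[cols]
        _, rep2 = filter_loq(shuffled)
        assert set(rep.index[rep.excluded]) == set(rep2.index[rep2.excluded])


class TestLogTransform:
    def test_values_and_round_trip(self):
        panel = make_panel([[np.e, 1.0], [1.0, np.e**2]])
        logged = log_transform(panel)
        assert logged.values.iloc[0, 0] == pytest.approx(1.0)
        assert logged.values.iloc[0, 1] == pytest.approx(0.0)
        back = np.exp(logged.values.to_numpy())
        assert np.allclose(back, panel.values.to_numpy(), atol=1e-12)
        assert logged.scale == "log"

    def test_rejects_non_positive_and_names_cell(self):
        panel = make_panel([[1.0, 2.0], [0.0, 3.0]])
        with pytest.raises(ValueError, match="B01"):
            log_transform(panel)


class TestImputeCensored:
    def test_no_censored_cells_unchanged(self):
        panel = make_panel(np.random.default_rng(3).normal(size=(30, 3)),
                           loq=-10.0, scale="log")
        out = impute_censored(panel)
        pd.testing.assert_frame_equal(out.values, panel.values)

    def test_independent_case_matches_truncated_normal_mean(self):
        # independent biomarkers, censoring at the marginal 30% quantile:
        # the imputed value must equal the closed form mu - sd*phi/Phi
        mu, sd = 1.3, 0.8
        q = mu + sd * stats.norm.ppf(0.3)
        rng = np.random.default_rng(4)
        x = rng.normal(mu, sd, size=(500, 2))
        cens = x < q
        vals = np.where(cens, q, x)
        panel = make_panel(vals, loq=q, censored=cens, scale="log")
        names = panel.biomarkers
        params = (
            pd.Series(mu, index=names),
            pd.Series(sd, index=names),
            pd.DataFrame(np.eye(2), index=names, columns=names),
        )
        out = impute_censored(panel, params=params)
        alpha = (q - mu) / sd
        closed_form = mu - sd * stats.norm.pdf(alpha) / stats.norm.cdf(alpha)
        imputed = out.values.to_numpy()[cens]
        assert np.allclose(imputed, closed_form, atol=1e-10)

    def test_imputed_never_exceeds_log_loq(self):
        cfg = GeneratorConfig(n_samples=300, n_biomarkers=10, blocks=(4, 3),
                              censoring_quantile=0.35, missing_rate=0.0, seed=5)
        panel, _, _ = generate_panel(cfg)
        logged = log_transform(panel)
        out = impute_censored(logged)
        cens = panel.censored.to_numpy()
        vals = out.values.to_numpy()
        bound = np.broadcast_to(out.loq.to_numpy(), vals.shape)
        assert np.all(vals[cens] <= bound[cens] + 1e-12)

    def test_conditional_beats_loq_half_substitution(self):
        # RMSE against the generator's latent truth, correlated biomarkers
        # (positive partial-correlation regime, so conditioning is informative)
        cfg = GeneratorConfig(n_samples=400, n_biomarkers=12, blocks=(4, 4),
                              rho=0.3, censoring_quantile=0.3, missing_rate=0.0,
                              seed=6)
        panel, _, truth = generate_panel(cfg)
        logged = log_transform(panel)
        out = impute_censored(logged)
        cens = panel.censored.to_numpy()
        true_log = np.log(truth.true_values.to_numpy())
        rmse_cond = np.sqrt(np.mean((out.values.to_numpy()[cens] - true_log[cens]) ** 2))
        loq_half = np.log(np.broadcast_to(panel.loq.to_numpy() / 2.0, cens.shape))
        rmse_half = np.sqrt(np.mean((loq_half[cens] - true_log[cens]) ** 2))
        assert rmse_cond < rmse_half

    def test_random_draw_is_seeded_and_truncated(self):
        cfg = GeneratorConfig(n_samples=150, n_biomarkers=6, blocks=(3,),
                              censoring_quantile=0.3, missing_rate=0.0, seed=7)
        panel, _, _ = generate_panel(cfg)
        logged = log_transform(panel)
        a = impute_censored(logged, random_draw=True, seed=42)
        b = impute_censored(logged, random_draw=True, seed=42)
        pd.testing.assert_frame_equal(a.values, b.values)
        cens = panel.censored.to_numpy()
        bound = np.broadcast_to(a.loq.to_numpy(), cens.shape)
        assert np.all(a.values.to_numpy()[cens] <= bound[cens])


class TestImputeMissing:
    def test_no_missing_unchanged(self):
        panel = make_panel(np.random.default_rng(8).normal(size=(40, 3)),
                           scale="log")
        out = impute_missing(panel)
        pd.testing.assert_frame_equal(out.values, panel.values)

    def test_exact_recovery_under_perfect_collinearity(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        vals = np.column_stack([x, 2.0 * x, rng.normal(size=100)])
        miss = np.zeros((100, 3), bool)
        miss[:10, 1] = True
        vals_masked = vals.copy()
        vals_masked[:10, 1] = np.nan
        panel = make_panel(vals_masked, missing=miss, scale="log")
        out = impute_missing(panel)
        assert np.allclose(out.values.to_numpy()[:10, 1], 2.0 * x[:10], atol=1e-8)
        assert not out.missing.to_numpy().any()

    def test_beats_column_mean_imputation(self):
        cfg = GeneratorConfig(n_samples=400, n_biomarkers=12, blocks=(4, 4),
                              rho=0.35, censoring_quantile=0.0, missing_rate=0.05,
                              seed=10)
        panel, _, truth = generate_panel(cfg)
        logged = log_transform(panel)
        out = impute_missing(logged)
        miss = panel.missing.to_numpy()
        true_log = np.log(truth.true_values.to_numpy())
        rmse_reg = np.sqrt(np.mean((out.values.to_numpy()[miss] - true_log[miss]) ** 2))
        col_mean = np.nanmean(np.where(miss, np.nan, logged.values.to_numpy()), axis=0)
        mean_filled = np.broadcast_to(col_mean, miss.shape)
        rmse_mean = np.sqrt(np.mean((mean_filled[miss] - true_log[miss]) ** 2))
        assert rmse_reg < rmse_mean

    def test_sample_with_everything_missing_rejected(self):
        vals = np.random.default_rng(11).normal(size=(20, 3))
        miss = np.zeros((20, 3), bool)
        miss[5, :] = True
        vals[5, :] = np.nan
        panel = make_panel(vals, missing=miss, scale="log")
        with pytest.raises(ValueError, match="all biomarkers missing"):
            impute_missing(panel)


class TestCorrectOutliers:
    def test_values_within_bounds_unchanged(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(200, 4))
        panel = make_panel(vals, scale="log")
        out, counts = correct_outliers(panel)
        if counts.sum() == 0:
            pd.testing.assert_frame_equal(out.values, panel.values)

    def test_extreme_value_moved_to_boundary(self):
        vals = np.random.default_rng(13).normal(size=(101, 1))
        med = np.median(vals)
        mad = np.median(np.abs(vals - med)) * 1.4826
        vals[0, 0] = med + 10 * mad
        panel = make_panel(vals, scale="log")
        out, counts = correct_outliers(panel, z_cut=4.0)
        # winsorized to the z = 4 boundary of the modified column
        v = out.values.to_numpy()[:, 0]
        med2 = np.median(panel.values.to_numpy()[:, 0])
        mad2 = np.median(np.abs(panel.values.to_numpy()[:, 0] - med2)) * 1.4826
        assert v[0] == pytest.approx(med2 + 4 * mad2)
        assert counts["B01"] >= 1

    def test_zero_mad_skipped_with_warning(self):
        vals = np.ones((30, 1))
        panel = make_panel(vals, scale="log")
        with pytest.warns(UserWarning, match="MAD is zero"):
            out, counts = correct_outliers(panel)
        assert counts["B01"] == 0

    def test_order_statistics_preserved_off_the_tails(self):
        rng = np.random.default_rng(14)
        vals = rng.standard_t(df=2, size=(300, 3))  # heavy tails
        panel = make_panel(vals, scale="log")
        out, _ = correct_outliers(panel)
        a = panel.values.to_numpy()
        b = out.values.to_numpy()
        for j in range(3):
            assert np.array_equal(np.argsort(a[:, j], kind="stable")[50:-50],
                                  np.argsort(b[:, j], kind="stable")[50:-50])


class TestAdjustCovariates:
    def test_residuals_orthogonal_to_numeric_covariates(self, small_dataset):
        panel, covars, _ = small_dataset
        logged = log_transform(panel.subset(panel.biomarkers[:5]))
        filled = impute_missing(impute_censored(logged))
        adjusted = adjust_covariates(filled, covars)
        for col in ("age", "bmi"):
            x = covars[col].to_numpy(dtype=float)
            for b in adjusted.biomarkers:
                r = np.corrcoef(adjusted.values[b], x)[0, 1]
                assert abs(r) < 1e-10

    def test_zero_effect_covariates_change_little(self):
        cfg = GeneratorConfig(n_samples=400, n_biomarkers=6, blocks=(3,),
                              censoring_quantile=0.0, missing_rate=0.0,
                              covariate_effects=None, creatinine_exponent=0.0,
                              seed=15)
        panel, covars, _ = generate_panel(cfg)
        logged = log_transform(panel)
        adjusted = adjust_covariates(logged, covars)
        centered = (logged.values - logged.values.mean()).to_numpy()
        # residuals deviate from the centered values only by the chance
        # fit of ~9 design columns on 400 samples (R^2 of a few percent)
        diff = adjusted.values.to_numpy() - centered
        assert np.sum(diff**2) / np.sum(centered**2) < 0.05

    def test_creatinine_dilution_removed(self):
        # planted shared dilution inflates marginal dependence; adjustment
        # must bring partial correlations closer to the planted truth
        cfg = GeneratorConfig(n_samples=800, n_biomarkers=10, blocks=(4,),
                              rho=0.3, censoring_quantile=0.0, missing_rate=0.0,
                              creatinine_exponent=1.0, seed=16)
        panel, covars, truth = generate_panel(cfg)
        logged = log_transform(panel)
        planted = truth.partial_correlation.to_numpy()

        def pc_dist(p):
            S = np.corrcoef(p.values.to_numpy(), rowvar=False)
            pc = partial_correlations(np.linalg.inv(S))
            return np.linalg.norm(pc - planted)

        adjusted = adjust_covariates(logged, covars)
        assert pc_dist(adjusted) < pc_dist(logged)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        panel = make_panel(np.random.default_rng(17).lognormal(size=(60, 4)),
                           scale="log")
        out = standardize(panel)
        assert np.all(np.abs(out.values.mean()) < 1e-12)
        assert np.allclose(out.values.std(ddof=1), 1.0, atol=1e-12)

    def test_location_invariance_and_idempotence(self):
        rng = np.random.default_rng(18)
        vals = rng.normal(size=(50, 3))
        a = standardize(make_panel(vals, scale="log"))
        b = standardize(make_panel(vals + 7.5, scale="log"))
        assert np.allclose(a.values, b.values, atol=1e-12)
        twice = standardize(a)
        assert np.allclose(twice.values, a.values, atol=1e-12)

    def test_zero_variance_rejected_by_name(self):
        vals = np.random.default_rng(19).normal(size=(30, 2))
        vals[:, 1] = 3.14
        with pytest.raises(ValueError, match="B02"):
            standardize(make_panel(vals, scale="log"))


class TestPipeline:
    def test_clean_panel_reduces_to_log_plus_standardize(self):
        rng = np.random.default_rng(20)
        vals = np.exp(rng.normal(size=(100, 5)) * 0.5)  # no extreme tails
        panel = make_panel(vals)
        prepared, report = preprocess_pipeline(panel, covariates=None)
        if report["n_winsorized"].sum() == 0:
            expected = standardize(log_transform(panel))
            assert np.allclose(prepared.values, expected.values, atol=1e-12)
        assert not report["exclusions"]["excluded"].any()

    def test_full_chain_on_generated_data(self, small_dataset):
        panel, covars, _ = small_dataset
        prepared, report = preprocess_pipeline(panel, covars)
        assert prepared.scale == "standardized"
        assert np.all(np.abs(prepared.values.mean()) < 1e-10)
        assert not prepared.values.isna().any().any()
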