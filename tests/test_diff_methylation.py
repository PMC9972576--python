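"""Design construction, per-probe OLS, empirical-Bayes moderation (checked
against a frozen limma reference) and the CpG-set rank test."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylstab.diff_methylation import (
    EBayesParams,
    build_design,
    call_dmps,
    ebayes_moderate,
    estimate_ebayes_params,
    fit_probes,
    set_rank_test,
    trigamma_inverse,
)
from methylstab.io_model import BetaMatrix, CpGSet, SampleSheet

DATA = Path(__file__).parent / "data"


class TestBuildDesign:
    def test_full_cohort_design(self, small_cohort):
        beta, sheet, _, reference, truth = small_cohort
        from methylstab.cell_deconvolution import deconvolve_samples

        cells = deconvolve_samples(beta.data, reference)
        design = build_design(sheet, cells)
        assert design.shape == (92, 10)  # 1+1+3 dummies + 5 cell columns
        assert np.linalg.matrix_rank(design.to_numpy()) == 10
        assert "cell_Neu" not in design.columns

    def test_zero_variance_column_dropped(self, tiny_sheet):
        df = tiny_sheet.data.copy()
        df["sex"] = "F"
        with pytest.warns(UserWarning, match="zero-variance.*sex"):
            design = build_design(SampleSheet(df))
        assert "sex_M" not in design.columns

    def test_row_order_follows_sheet(self, tiny_sheet):
        d1 = build_design(tiny_sheet)
        shuffled = SampleSheet(tiny_sheet.data.iloc[::-1].reset_index(drop=True))
        d2 = build_design(shuffled)
        pd.testing.assert_frame_equal(d1, d2.loc[d1.index])

    def test_rank_deficiency_reported(self, tiny_sheet):
        df = tiny_sheet.data.copy()
        df["dup"] = (df["timepoint"] == "T2").astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            build_design(SampleSheet(df), extra_numeric=["dup"])


class TestFitProbes:
    def test_probe_equal_to_time_column_is_exact(self, tiny_sheet):
        design = build_design(tiny_sheet)
        y = design["timepoint_T2"].to_numpy()
        beta = pd.DataFrame([y], index=["cgX"], columns=design.index)
        fit = fit_probes(beta, design)
        j = fit.columns.index("timepoint_T2")
        assert fit.coef[0, j] == pytest.approx(1.0, abs=1e-12)
        assert fit.s2[0] == pytest.approx(0.0, abs=1e-20)

    def test_agrees_with_statsmodels_ols(self, small_cohort):
        import statsmodels.api as sm

        beta, sheet, *_ = small_cohort
        design = build_design(sheet)
        fit = fit_probes(beta, design)
        rng = np.random.default_rng(0)
        X = design.to_numpy()
        for i in rng.choice(beta.shape[0], size=100, replace=False):
            y = beta.data[design.index].iloc[i].to_numpy()
            res = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit.coef[i], res.params, atol=1e-10)
            assert fit.s2[i] == pytest.approx(res.mse_resid, abs=1e-10)
            np.testing.assert_allclose(
                fit.stdev_unscaled[i] * np.sqrt(fit.s2[i]), res.bse, atol=1e-10
            )

    def test_null_probe_t_statistics_follow_t(self, tiny_sheet):
        rng = np.random.default_rng(1)
        design = build_design(tiny_sheet)
        n, p = design.shape
        m = 4000
        beta = pd.DataFrame(rng.normal(0.5, 0.03, size=(m, n)).clip(0, 1),
                            index=[f"cg{i}" for i in range(m)], columns=design.index)
        fit = fit_probes(beta, design)
        j = fit.columns.index("timepoint_T2")
        t = fit.coef[:, j] / (fit.stdev_unscaled[:, j] * np.sqrt(fit.s2))
        ks = stats.kstest(t, stats.t(df=n - p).cdf)
        assert ks.pvalue > 0.01

    def test_missing_values_refit_or_skipped(self, small_cohort):
        beta, sheet, *_ = small_cohort
        design = build_design(sheet)
        data = beta.data.copy()
        data.iloc[0, 0] = np.nan                 # one missing sample -> refit
        data.iloc[1, :40] = np.nan               # excess missingness -> skip
        fit = fit_probes(BetaMatrix(data), design)
        assert not fit.skipped[0] and np.isfinite(fit.s2[0])
        assert fit.df_resid[0] == 91 - design.shape[1]
        assert fit.skipped[1]


class TestEBayes:
    def test_matches_frozen_limma_reference(self):
        y = pd.read_csv(DATA / "limma_fixture_y.csv", index_col=0)
        X = pd.read_csv(DATA / "limma_fixture_design.csv", index_col=0)
        expected = pd.read_csv(DATA / "limma_fixture_expected.csv")
        fit = fit_probes(y, X)
        params, table = ebayes_moderate(fit, coef_name="group")
        assert params.d0 == pytest.approx(expected["d0"][0], rel=1e-9)
        assert params.s0_sq == pytest.approx(expected["s0_sq"][0], rel=1e-9)
        for mine, ref in [("coef_time", "coef_group"), ("s2", "s2"),
                          ("s2_post", "s2_post"), ("t_mod", "t_mod"),
                          ("p_value", "p_value")]:
            np.testing.assert_allclose(table[mine], expected[ref], atol=1e-10)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        d0, s0, dg = 4.0, 0.01, 10
        sigma2 = s0 * d0 / rng.chisquare(d0, size=10_000)
        s2 = sigma2 * rng.chisquare(dg, size=10_000) / dg
        params = estimate_ebayes_params(s2, dg)
        assert 3.4 <= params.d0 <= 4.6
        assert params.s0_sq == pytest.approx(s0, rel=0.1)

    def test_homogeneous_variances_give_infinite_prior(self):
        rng = np.random.default_rng(3)
        dg = 20
        s2 = 0.01 * rng.chisquare(dg, size=5000) / dg  # all true variances equal
        params = estimate_ebayes_params(s2, dg)
        # sampling variability of log s2 is fully explained by chi2 noise
        assert params.d0 > 50 or np.isinf(params.d0)

    def test_infinite_prior_pools_variance(self, tiny_sheet):
        rng = np.random.default_rng(4)
        design = build_design(tiny_sheet)
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(200, 12)),
                            index=[f"cg{i}" for i in range(200)], columns=design.index)
        fit = fit_probes(beta, design)
        params, table = ebayes_moderate(
            fit, params=EBayesParams(np.inf, 0.02)
        )
        np.testing.assert_allclose(table["s2_post"], 0.02)
        assert np.isinf(table["df_total"]).all()

    def test_small_prior_df_approaches_ordinary_t(self, tiny_sheet):
        rng = np.random.default_rng(5)
        design = build_design(tiny_sheet)
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(200, 12)),
                            index=[f"cg{i}" for i in range(200)], columns=design.index)
        fit = fit_probes(beta, design)
        _, table = ebayes_moderate(fit, params=EBayesParams(1e-9, 0.02))
        j = fit.columns.index("timepoint_T2")
        t_ord = fit.coef[:, j] / (fit.stdev_unscaled[:, j] * np.sqrt(fit.s2))
        np.testing.assert_allclose(table["t_mod"], t_ord, rtol=1e-4)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (0.1, 1.0, 5.0, 50.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-8)


class TestCallDMPs:
    def test_time_duplicate_probe_is_dmp(self, small_cohort):
        beta, sheet, *_ = small_cohort
        design = build_design(sheet)
        data = beta.data.copy()
        data.loc["cg_time"] = design["timepoint_T2"].reindex(data.columns).to_numpy() * 0.5
        fit = fit_probes(BetaMatrix(data), design)
        _, table = ebayes_moderate(fit)
        out = call_dmps(table)
        assert out.loc["cg_time", "is_dmp"]
        assert out.loc["cg_time", "p_value"] < 1e-20

    def test_delta_beta_matches_paired_mean_difference(self, small_cohort):
        beta, sheet, *_ = small_cohort
        from methylstab.io_model import align_pairs

        design = build_design(sheet)
        fit = fit_probes(beta, design)
        _, table = ebayes_moderate(fit)
        out = call_dmps(table, beta, sheet)
        view = align_pairs(beta, sheet)
        expected = (view.t2 - view.t1).mean(axis=1)
        np.testing.assert_allclose(out["delta_beta"].to_numpy(), expected, atol=1e-12)

    def test_all_null_cohort_has_no_dmps(self, tiny_sheet):
        rng = np.random.default_rng(6)
        design = build_design(tiny_sheet)
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(3000, 12)),
                            index=[f"cg{i}" for i in range(3000)], columns=design.index)
        fit = fit_probes(beta, design)
        _, table = ebayes_moderate(fit)
        out = call_dmps(table)
        assert out["is_dmp"].sum() <= 3


class TestSetRankTest:
    def test_extreme_down_set(self, small_cohort):
        beta, sheet, *_ = small_cohort
        design = build_design(sheet)
        fit = fit_probes(beta, design)
        _, table = ebayes_moderate(fit)
        top = table["t_mod"].nsmallest(100).index
        res = set_rank_test(table["t_mod"], CpGSet("top", tuple(top)), alternative="down")
        assert res["p_value"] < 1e-30

    def test_random_set_is_null(self, small_cohort):
        beta, sheet, *_ = small_cohort
        design = build_design(sheet)
        fit = fit_probes(beta, design)
        _, table = ebayes_moderate(fit)
        rng = np.random.default_rng(7)
        ps = []
        for i in range(50):
            members = tuple(rng.choice(table.index, size=60, replace=False))
            ps.append(set_rank_test(table["t_mod"], CpGSet(f"r{i}", members),
                                    alternative="mixed")["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_set_warns_and_uses_exact(self, small_cohort):
        beta, sheet, *_ = small_cohort
        design = build_design(sheet)
        fit = fit_probes(beta, design)
        _, table = ebayes_moderate(fit)
        members = tuple(table.index[:3])
        with pytest.warns(UserWarning, match="exact"):
            res = set_rank_test(table["t_mod"], CpGSet("tiny", members))
        assert 0 <= res["p_value"] <= 1

    def test_empty_intersection_rejected(self, small_cohort):
        beta, sheet, *_ = small_cohort
        design = build_design(sheet)
        fit = fit_probes(beta, design)
        _, table = ebayes_moderate(fit)
        with pytest.raises(ValueError, match="no members"):
            set_rank_test(table["t_mod"], CpGSet("none", ("nope1", "nope2")))
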