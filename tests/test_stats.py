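"""Reliability (ICC), mixed models, within/between decomposition, correlation."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sfskit import datasets
from sfskit import stats as st


def _cohort_long(seed, *, n_birds=12, n_days=11, sd_bird=2.0, sd_resid=1.5,
                 beta_within=0.0098, beta_between=-0.0155, day_slope=0.0,
                 reinf_mean=261.0, reinf_sd_between=138.0,
                 reinf_sd_within=60.0):
    """Bird-day table at the reference cohort's scales, from a known model."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_birds):
        sex = "M" if i % 2 == 0 else "F"
        bird_reinf = rng.normal(reinf_mean, reinf_sd_between)
        intercept = 80 + rng.normal(0, sd_bird) + 2.5 * (sex == "M")
        for day in range(1, n_days + 1):
            reinf = bird_reinf + rng.normal(0, reinf_sd_within) \
                + day_slope * day
            y = (intercept + beta_within * (reinf - bird_reinf)
                 + beta_between * bird_reinf + rng.normal(0, sd_resid))
            rows.append((f"B{i:02d}", sex, day, reinf, y))
    return pd.DataFrame(rows, columns=["bird_id", "sex", "day",
                                       "reinforcements", "dusk_mass_g"])


class TestIcc:
    def test_pure_bird_effects_give_unity(self):
        rng = np.random.default_rng(0)
        matrix = np.tile(rng.normal(80, 5, 12)[:, None], (1, 11))
        assert st.icc_single_absolute(matrix).icc == pytest.approx(1.0)

    def test_constant_matrix_undefined(self):
        with pytest.raises(ValueError, match="zero total variance"):
            st.icc_single_absolute(np.full((5, 5), 80.0))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            st.icc_single_absolute(np.array([[1.0, 2.0]]))

    def test_rows_with_missing_days_dropped(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (10, 5)) + rng.normal(0, 2, 10)[:, None]
        X2 = X.copy()
        X2 = np.vstack([X2, np.full(5, np.nan)])
        a = st.icc_single_absolute(X)
        b = st.icc_single_absolute(X2)
        assert a.icc == pytest.approx(b.icc)
        assert b.n_subjects == 10

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_pingouin_point_and_interval(self, seed):
        import pingouin as pg
        rng = np.random.default_rng(seed)
        X = (rng.normal(0, 2, 12)[:, None] + rng.normal(0, 1, (12, 11))
             + rng.normal(0, 0.5, 11)[None, :])
        mine = st.icc_single_absolute(X)
        long = pd.DataFrame({"s": np.repeat(np.arange(12), 11),
                             "r": np.tile(np.arange(11), 12),
                             "y": X.ravel()})
        ref = pg.intraclass_corr(long, targets="s", raters="r", ratings="y")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert mine.icc == pytest.approx(float(row.ICC), abs=1e-9)
        lo, hi = row.CI95
        assert mine.ci_low == pytest.approx(float(lo), abs=0.01)
        assert mine.ci_high == pytest.approx(float(hi), abs=0.01)

    def test_limit_equals_variance_ratio(self):
        # no day effect, large sample: ICC -> sigma_b^2/(sigma_b^2+sigma_e^2)
        rng = np.random.default_rng(2)
        n, k = 600, 80
        X = (rng.normal(0, np.sqrt(0.85), n)[:, None]
             + rng.normal(0, np.sqrt(0.15), (n, k)))
        assert st.icc_single_absolute(X).icc == pytest.approx(0.85, abs=0.03)


class TestRandomInterceptModel:
    def test_constant_response_gives_zero_slopes_and_variance(self):
        df = _cohort_long(0)
        df["dusk_mass_g"] = 80.0
        m = st.fit_random_intercept_model(df, "dusk_mass_g",
                                          ["reinforcements", "sex"])
        assert m.beta("reinforcements") == pytest.approx(0.0, abs=1e-8)
        assert m.beta("sex_M") == pytest.approx(0.0, abs=1e-8)
        assert m.var_bird == pytest.approx(0.0, abs=1e-8)

    def test_reduces_to_ols_without_bird_variance(self):
        # balanced design, zero true bird variance: REML variance collapses
        # and fixed effects equal ordinary least squares
        import statsmodels.api as sm_api
        df = _cohort_long(3, sd_bird=0.0, beta_between=0.0098,
                          n_birds=20, n_days=12)
        df["male"] = (df.sex == "M").astype(float)
        m = st.fit_random_intercept_model(df, "dusk_mass_g",
                                          ["reinforcements", "sex"])
        X = sm_api.add_constant(df[["reinforcements", "male"]])
        ols = sm_api.OLS(df["dusk_mass_g"], X).fit()
        assert m.var_bird == pytest.approx(0.0, abs=0.2)
        assert m.beta("reinforcements") == pytest.approx(
            ols.params["reinforcements"], rel=1e-2)
        assert m.beta("sex_M") == pytest.approx(ols.params["male"], abs=0.05)

    def test_day_slope_recovered_within_two_se(self):
        df = _cohort_long(5, day_slope=-3.37, reinf_sd_within=40.0)
        m = st.fit_random_intercept_model(df, "reinforcements",
                                          ["day", "sex"])
        fe = m.effect("day")
        assert abs(fe.beta - (-3.37)) < 2 * fe.se

    def test_satterthwaite_matches_lmertest(self, tmp_path):
        df = _cohort_long(7)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        m = st.fit_random_intercept_model(df, "dusk_mass_g",
                                          ["reinforcements", "sex"])
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv('{csv}')
            d$sex <- relevel(factor(d$sex), ref='F')
            m <- lmer(dusk_mass_g ~ reinforcements + sex + (1|bird_id),
                      data=d, REML=TRUE)
            co <- summary(m)$coefficients
            write.csv(co, '{tmp_path}/ref.csv')
        """)
        (tmp_path / "m.R").write_text(rscript)
        subprocess.run(["Rscript", str(tmp_path / "m.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
        for ours, theirs in [("reinforcements", "reinforcements"),
                             ("sex_M", "sexM")]:
            fe = m.effect(ours)
            assert fe.beta == pytest.approx(ref.loc[theirs, "Estimate"],
                                            rel=1e-4)
            assert fe.se == pytest.approx(ref.loc[theirs, "Std. Error"],
                                          rel=1e-3)
            assert fe.df_den == pytest.approx(ref.loc[theirs, "df"], rel=0.02)
            assert fe.p == pytest.approx(ref.loc[theirs, "Pr(>|t|)"],
                                         rel=0.05, abs=1e-6)

    def test_single_subject_rejected(self):
        df = _cohort_long(0, n_birds=1)
        with pytest.raises(ValueError):
            st.fit_random_intercept_model(df, "dusk_mass_g", ["day"])


class TestCentring:
    @given(hst.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_additive_decomposition(self, seed):
        df = _cohort_long(seed, n_birds=5, n_days=4)
        dec = st.within_between_decompose(df, "reinforcements")
        np.testing.assert_allclose(
            (dec.reinforcements_within + dec.reinforcements_between)
            .to_numpy(),
            dec.reinforcements.to_numpy(), rtol=1e-14, atol=1e-12)
        for _, grp in dec.groupby("bird_id"):
            assert grp.reinforcements_within.mean() == pytest.approx(
                0.0, abs=1e-9)

    def test_single_subject_between_is_constant_mean(self):
        df = _cohort_long(1, n_birds=1)
        dec = st.within_between_decompose(df, "reinforcements")
        assert dec.reinforcements_between.nunique() == 1
        assert dec.reinforcements_between.iloc[0] == pytest.approx(
            df.reinforcements.mean())


class TestThreeModelSequence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_coefficient_identities_hold(self, seed):
        df = _cohort_long(seed)
        seq = st.fit_three_model_sequence(df, "dusk_mass_g", "reinforcements")
        assert seq.identity_max_abs_diff < 1e-6

    def test_opposite_within_between_signs_recovered_within_two_se(self):
        df = _cohort_long(11, beta_within=0.0098, beta_between=-0.0155)
        seq = st.fit_three_model_sequence(df, "dusk_mass_g", "reinforcements")
        w = seq.decomposed.effect("reinforcements_within")
        b = seq.decomposed.effect("reinforcements_between")
        assert abs(w.beta - 0.0098) < 2 * w.se
        assert abs(b.beta - (-0.0155)) < 2 * b.se

    def test_constant_between_component_dropped(self):
        # predictor varies only with day, so every bird's mean is identical
        df = _cohort_long(4)
        df["reinforcements"] = df.groupby("bird_id").cumcount() * 10.0
        with pytest.warns(UserWarning, match="zero variance"):
            seq = st.fit_three_model_sequence(df, "dusk_mass_g",
                                              "reinforcements")
        w = seq.decomposed.beta("reinforcements_within")
        assert w == pytest.approx(seq.raw.beta("reinforcements"), rel=1e-6)

    def test_within_slope_estimator_unbiased_at_cohort_scale(self):
        betas, ses = [], []
        for seed in range(40):
            df = _cohort_long(1000 + seed)
            dec = st.within_between_decompose(df, "reinforcements")
            m = st.fit_random_intercept_model(
                dec, "dusk_mass_g",
                ["reinforcements_within", "reinforcements_between", "sex"])
            fe = m.effect("reinforcements_within")
            betas.append(fe.beta)
            ses.append(fe.se)
        bias = np.mean(betas) - 0.0098
        assert abs(bias) < 0.1 * 0.0098 + 2 * np.std(betas) / np.sqrt(40)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(5.0)
        r = st.pearson_corr(x, x)
        assert r.r == pytest.approx(1.0)
        assert r.df == 3

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            st.pearson_corr(np.ones(5), np.arange(5.0))

    def test_cohort_dawn_dusk_correlation(self):
        tbl = datasets.load_cohort_descriptives()
        r = st.pearson_corr(tbl.dawn_mass_mean, tbl.dusk_mass_mean)
        assert round(r.r, 2) == 0.98
        assert r.df == 10
        assert r.p < 0.0001

    def test_cohort_gain_loss_correlation(self):
        tbl = datasets.load_cohort_descriptives()
        r = st.pearson_corr(tbl.daily_gain_mean, tbl.nightly_loss_mean)
        assert round(r.r, 2) == 0.99
        assert r.p < 0.0001
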