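"""Random-intercept LMM: estimation, F tests, contrasts and the t test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from pupilmw.lmm import (
    LMMSpec,
    RandomInterceptLMM,
    anova_interaction,
    fit_lmm,
    posthoc_pairwise,
    split_half,
    two_sample_t,
)


def simulate_summaries(
    rng, n_subjects=10, n_epochs=30, s_u=0.2, s_e=0.3,
    slope_b=0.1, level_c=0.05, conditions=("a", "b", "c"),
):
    """Tidy epoch-summary table from the model's own data-generating process."""
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, s_u)
        for e in range(n_epochs):
            cond = conditions[rng.integers(len(conditions))]
            for pos in (0.0, 1.0, 2.0):
                mu = slope_b * (cond == "b") * pos + level_c * (cond == "c") + 0.02 * pos
                rows.append(
                    dict(subject_id=f"s{s:02d}", reference_id=f"e{s}_{e}",
                         condition=cond, position=pos,
                         value_mm=mu + u + rng.normal(0, s_e))
                )
    return pd.DataFrame(rows)


def demean_by_subject(df):
    out = df.copy()
    out["value_mm"] -= out.groupby("subject_id")["value_mm"].transform("mean")
    return out


class TestFit:
    def test_zero_subject_variance_reduces_to_ols(self):
        """With subject effects exactly removed, the profiled ML fit lands on
        the boundary and reproduces the normal-equations OLS solution."""
        rng = np.random.default_rng(1)
        df = demean_by_subject(simulate_summaries(rng, s_u=0.4))
        model = RandomInterceptLMM.from_summaries(df, LMMSpec(reference="a"))
        res = model.fit()
        assert res.sigma2_u == 0.0
        beta_ols, *_ = oracles.ols_fit(model.exog, model.endog)
        assert np.allclose(res.fe_params.to_numpy(), beta_ols, rtol=1e-8, atol=1e-12)

    def test_balanced_noiseless_table_recovers_cell_means(self):
        """Zero-noise two-condition fixture: coefficients are exact cell-mean
        arithmetic (intercept 0.4, condition offset 0.25, slopes 0.1/0.05)."""
        rows = []
        for s in ("s1", "s2"):
            for e in range(3):
                for cond, level, slope in (("a", 0.4, 0.1), ("b", 0.65, 0.15)):
                    for pos in (0.0, 1.0, 2.0):
                        rows.append(
                            dict(subject_id=s, reference_id=f"{cond}{e}", condition=cond,
                                 position=pos, value_mm=level + slope * pos)
                        )
        res = fit_lmm(pd.DataFrame(rows), LMMSpec(reference="a"))
        assert res.fe_params["Intercept"] == pytest.approx(0.4, abs=1e-10)
        assert res.fe_params["C[b]"] == pytest.approx(0.25, abs=1e-10)
        assert res.fe_params["position"] == pytest.approx(0.1, abs=1e-10)
        assert res.fe_params["C[b]:position"] == pytest.approx(0.05, abs=1e-10)
        assert res.sigma2_e < 1e-16

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_matches_statsmodels_mixedlm(self, seed):
        """Profiled fit agrees with the general-purpose reference
        implementation (statsmodels MixedLM, ML) on random datasets."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(seed)
        df = simulate_summaries(rng, n_subjects=8, n_epochs=20)
        res = fit_lmm(df, LMMSpec(reference="a"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf = smf.mixedlm(
                "value_mm ~ C(condition, Treatment('a')) * position",
                df, groups=df["subject_id"],
            ).fit(reml=False, method="powell")
        assert np.allclose(res.fe_params.to_numpy(), mf.fe_params.to_numpy(), atol=1e-6)
        assert res.sigma2_e == pytest.approx(mf.scale, rel=1e-4)
        assert res.sigma2_u == pytest.approx(
            float(mf.cov_re.iloc[0, 0]), rel=1e-4, abs=1e-6
        )

    def test_variance_component_recovery(self):
        """Median estimates over 200 replicates stay within 20% of the true
        variance components (42 subjects, sigma2_u=0.04, sigma2_e=0.01)."""
        rng = np.random.default_rng(99)
        s2u, s2e = [], []
        for _ in range(200):
            df = simulate_summaries(
                rng, n_subjects=42, n_epochs=6, s_u=0.2, s_e=0.1,
            )
            res = fit_lmm(df, LMMSpec(reference="a"))
            s2u.append(res.sigma2_u)
            s2e.append(res.sigma2_e)
        assert np.median(s2u) == pytest.approx(0.04, rel=0.20)
        assert np.median(s2e) == pytest.approx(0.01, rel=0.20)

    def test_reml_variance_exceeds_ml(self):
        rng = np.random.default_rng(5)
        df = simulate_summaries(rng, n_subjects=6, n_epochs=10)
        ml = fit_lmm(df, LMMSpec(reference="a"), reml=False)
        reml = fit_lmm(df, LMMSpec(reference="a"), reml=True)
        assert reml.sigma2_u >= ml.sigma2_u * 0.99

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(0)
        df = simulate_summaries(rng, n_subjects=4, n_epochs=5)
        df["position"] = 1.0  # position collinear with the intercept
        with pytest.raises(Exception, match="at least 2 positions"):
            fit_lmm(df, LMMSpec(reference="a"))
        x = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            RandomInterceptLMM(np.zeros(20), x, np.repeat(["a", "b"], 10))

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(0)
        df = simulate_summaries(rng, n_subjects=4, n_epochs=5)
        df.loc[0, "value_mm"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_lmm(df, LMMSpec(reference="a"))

    def test_summary_renders(self):
        rng = np.random.default_rng(2)
        res = fit_lmm(simulate_summaries(rng, 5, 8), LMMSpec(reference="a"))
        text = res.summary()
        assert "sigma2_u" in text and "condition:position" in text


class TestFTests:
    def test_interaction_f_equals_ols_partial_f_at_boundary(self):
        rng = np.random.default_rng(7)
        df = demean_by_subject(simulate_summaries(rng, s_u=0.3))
        model = RandomInterceptLMM.from_summaries(df, LMMSpec(reference="a"))
        res = model.fit()
        ft = anova_interaction(res)
        idx = model.term_slices["condition:position"]
        f_o, df1_o, df2_o, p_o = oracles.ols_partial_f(model.exog, model.endog, idx)
        assert ft.fvalue == pytest.approx(f_o, rel=1e-6)
        assert (ft.df1, ft.df2) == (df1_o, df2_o)
        assert ft.pvalue == pytest.approx(p_o, rel=1e-6)

    def test_residual_df_convention(self):
        rng = np.random.default_rng(3)
        df = simulate_summaries(rng, n_subjects=6, n_epochs=10)
        res = fit_lmm(df, LMMSpec(reference="a"))
        assert res.df_resid == len(df) - 6
        assert anova_interaction(res).df2 == len(df) - 6

    def test_interaction_absent_raises(self):
        x = np.column_stack([np.ones(40), np.tile([0.0, 1.0], 20)])
        model = RandomInterceptLMM(
            np.random.default_rng(0).normal(size=40), x, np.repeat(["a", "b"], 20)
        )
        with pytest.raises(ValueError, match="interaction"):
            anova_interaction(model.fit())

    def test_interaction_detects_true_slope_difference(self):
        rng = np.random.default_rng(21)
        df = simulate_summaries(rng, n_subjects=20, n_epochs=40, slope_b=0.15)
        assert anova_interaction(fit_lmm(df, LMMSpec(reference="a"))).pvalue < 1e-4


class TestPosthoc:
    def test_identical_groups_give_null_f(self):
        rows = []
        for s in ("s1", "s2", "s3"):
            for e in range(4):
                for cond in ("a", "b"):
                    rows.append(dict(subject_id=s, reference_id=f"{cond}{e}",
                                     condition=cond, position=1.0,
                                     value_mm=float(e)))
        ft = posthoc_pairwise(pd.DataFrame(rows), ("a", "b"), 1.0)
        assert ft.fvalue == pytest.approx(0.0, abs=1e-12)
        assert ft.pvalue == pytest.approx(1.0)

    def test_df2_is_pair_size_minus_two(self):
        rng = np.random.default_rng(8)
        df = simulate_summaries(rng, n_subjects=6, n_epochs=12)
        pair = df[df.condition.isin(["a", "b"]) & (df.position == 1.0)]
        ft = posthoc_pairwise(df, ("a", "b"), 1.0)
        assert ft.df2 == len(pair) - 2
        assert ft.df1 == 1

    def test_matches_pooled_t_squared_without_subject_effects(self):
        """On subject-free data the contrast F equals the classical two-group
        pooled t^2 (closed form) to near machine precision."""
        rng = np.random.default_rng(9)
        df = demean_by_subject(simulate_summaries(rng, n_subjects=8, n_epochs=15))
        sub = df[(df.position == 2.0) & df.condition.isin(["a", "c"])]
        x = sub.loc[sub.condition == "a", "value_mm"].to_numpy()
        y = sub.loc[sub.condition == "c", "value_mm"].to_numpy()
        ft = posthoc_pairwise(df, ("a", "c"), 2.0)
        assert ft.fvalue == pytest.approx(oracles.pooled_t_f(x, y), rel=1e-10)

    def test_empty_condition_raises(self):
        rng = np.random.default_rng(0)
        df = simulate_summaries(rng, n_subjects=4, n_epochs=5,
                                conditions=("a", "b"))
        with pytest.raises(ValueError, match="empty"):
            posthoc_pairwise(df, ("a", "zzz"), 1.0)


class TestSplitHalf:
    def test_within_subject_parity_split(self):
        rng = np.random.default_rng(10)
        # even per-subject epoch count: exact halves
        df = simulate_summaries(rng, n_subjects=2, n_epochs=4)
        halves = split_half(df)
        assert halves["even"][0].nobs == halves["odd"][0].nobs == len(df) // 2
        # odd per-subject count: each subject contributes one extra even epoch
        df = simulate_summaries(rng, n_subjects=2, n_epochs=5)
        halves = split_half(df)
        assert halves["even"][0].nobs == 2 * 3 * 3
        assert halves["odd"][0].nobs == 2 * 2 * 3

    def test_duplicate_epochs_give_identical_halves(self):
        rng = np.random.default_rng(11)
        base = simulate_summaries(rng, n_subjects=3, n_epochs=4)
        parts = []
        for ref, grp in base.groupby("reference_id", sort=False):
            parts.append(grp)
            parts.append(grp.assign(reference_id=f"{ref}_dup"))
        both = pd.concat(parts, ignore_index=True)
        halves = split_half(both)
        a, b = halves["even"][0], halves["odd"][0]
        assert np.allclose(a.fe_params.to_numpy(), b.fe_params.to_numpy())
        assert a.llf == pytest.approx(b.llf)

    def test_parity_is_deterministic(self):
        rng = np.random.default_rng(12)
        df = simulate_summaries(rng, n_subjects=4, n_epochs=9)
        h1 = split_half(df)
        h2 = split_half(df)
        assert h1["odd"][1].fvalue == h2["odd"][1].fvalue


class TestTwoSampleT:
    def test_equal_samples_give_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = two_sample_t(x, x)
        assert t == 0.0 and p == 1.0 and df == 6

    def test_textbook_fixture_matches_hand_computation(self):
        # means 5 and 3, pooled variance 2.5 -> t = 2 / sqrt(2.5 * 2/5) = 2
        x = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, df, p = two_sample_t(x, y)
        t_hand = 2.0 / np.sqrt(2.5 * (1 / 5 + 1 / 5))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == 8
        assert p == pytest.approx(2 * stats.t.sf(t_hand, 8), abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 30), rng.normal(0.3, 1, 25)
        t, df, p = two_sample_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_type_i_error_calibration(self):
        """Equal-mean simulation: rejection rate at alpha=.05 in [.03, .07]."""
        rng = np.random.default_rng(14)
        n_rep, n = 2000, 20
        x = rng.normal(size=(n_rep, n))
        y = rng.normal(size=(n_rep, n))
        res = stats.ttest_ind(x, y, axis=1, equal_var=True)
        ours = np.array([two_sample_t(x[i], y[i])[2] for i in range(0, n_rep, 50)])
        theirs = res.pvalue[range(0, n_rep, 50)]
        assert np.allclose(ours, theirs, atol=1e-12)
        rate = float(np.mean(res.pvalue < 0.05))
        assert 0.03 < rate < 0.07

    def test_degenerate_variance(self):
        assert two_sample_t([1.0, 1.0], [1.0, 1.0]) == (0.0, 2, 1.0)
        with pytest.raises(ZeroDivisionError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError, match="at least 2"):
            two_sample_t([1.0], [1.0, 2.0])
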