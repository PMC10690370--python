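"""Condition-effect models, contrasts, ordinal intensity fit, regression."""

import numpy as np
import pandas as pd
import pytest

from mvslab import (
    duration_regression,
    fit_condition_model,
    fit_ordinal_intensity,
    pairwise_contrasts,
    sample_peak_table,
)
from mvslab.errors import DesignError, InsufficientDataError
from mvslab.synth import VERTIGO_CATEGORIES, VertigoParams, synth_vertigo
from mvslab.synth import SubjectParams


def _balanced(values_by_cond, subject_offsets):
    rows = []
    for s, off in enumerate(subject_offsets):
        for cond, mu in values_by_cond.items():
            rows.append((mu + off, cond, f"S{s}"))
    v, c, s = zip(*rows)
    return list(v), list(c), list(s)


class TestConditionModel:
    def test_statsmodels_oracle_equivalence(self):
        """Coefficients, marginal means and F-test match an independent
        statsmodels OLS fit on a small noisy instance."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = sample_peak_table(n_subjects=6, seed=42)
        fit = fit_condition_model(df["value"], df["condition"], df["subject"])
        sm_df = df.assign(condition=df["condition"].astype(str))
        res = smf.ols("value ~ C(condition, Sum) + C(subject)", data=sm_df).fit()
        # marginal means: predictions averaged over subjects
        preds = []
        for cond in sorted(df["condition"].unique()):
            grid = pd.DataFrame({
                "condition": str(cond),
                "subject": sorted(df["subject"].unique()),
            })
            preds.append(res.predict(grid).mean())
        assert np.allclose(fit.emmeans["mean"], preds, rtol=1e-10)
        res_t = smf.ols("value ~ C(condition) + C(subject)", data=sm_df).fit()
        an = anova_lm(res_t)
        assert fit.p_value == pytest.approx(an.loc["C(condition)", "PR(>F)"], rel=1e-8)
        assert fit.f_stat == pytest.approx(an.loc["C(condition)", "F"], rel=1e-8)

    def test_balanced_marginal_means_equal_raw_means(self):
        df = sample_peak_table(n_subjects=5, seed=9)
        fit = fit_condition_model(df["value"], df["condition"], df["subject"])
        raw = df.groupby("condition")["value"].mean()
        for _, row in fit.emmeans.iterrows():
            assert row["mean"] == pytest.approx(raw[row["condition"]], rel=1e-12)

    def test_truth_recovery_with_subject_offsets(self):
        v, c, s = _balanced({20.0: -15.5, 120.0: -12.9, 300.0: -9.0},
                            [1.2, -0.4, 0.9, -1.7, 0.0, 0.5, -0.6, 0.1])
        fit = fit_condition_model(v, c, s)
        for cond, mu in ((20.0, -15.5), (120.0, -12.9), (300.0, -9.0)):
            row = fit.emmeans[fit.emmeans["condition"] == cond].iloc[0]
            assert row["mean"] == pytest.approx(mu, abs=1e-9)

    def test_all_identical_values_contract(self):
        v, c, s = _balanced({20.0: -5.0, 300.0: -5.0}, [0.0, 0.0, 0.0])
        fit = fit_condition_model(v, c, s)
        assert fit.f_stat == 0.0
        assert fit.p_value == 1.0

    def test_single_condition_rejected(self):
        with pytest.raises(DesignError):
            fit_condition_model([1, 2], [20.0, 20.0], ["a", "b"])

    def test_missing_cell_named(self):
        with pytest.raises(DesignError, match=r"\(S1, 120\)"):
            fit_condition_model([1, 2, 3], [20.0, 120.0, 20.0], ["S0", "S0", "S1"])

    def test_ci_coverage_nominal(self):
        """CIs cover the cohort's realized condition means at ~95%."""
        covered = total = 0
        for seed in range(300):
            df, truth = sample_peak_table(seed=seed, return_truth=True)
            fit = fit_condition_model(df["value"], df["condition"], df["subject"])
            for _, row in fit.emmeans.iterrows():
                total += 1
                covered += row["ci_low"] <= truth[row["condition"]] <= row["ci_high"]
        assert 0.92 <= covered / total <= 0.98


class TestContrasts:
    def test_percent_difference_arithmetic(self):
        v, c, s = _balanced({20.0: -15.5, 300.0: -9.0}, [0.3, -0.3, 0.0])
        fit = fit_condition_model(v, c, s)
        ct = pairwise_contrasts(fit)
        row = ct.iloc[0]
        assert row["percent_difference"] == pytest.approx(
            100.0 * (15.5 - 9.0) / 15.5, abs=1e-9
        )
        assert round(row["percent_difference"], 1) == 41.9

    def test_antisymmetry(self):
        df = sample_peak_table(seed=21)
        fit = fit_condition_model(df["value"], df["condition"], df["subject"])
        fwd = pairwise_contrasts(fit, pairs=[(20.0, 300.0)]).iloc[0]
        rev = pairwise_contrasts(fit, pairs=[(300.0, 20.0)]).iloc[0]
        assert fwd["difference"] == pytest.approx(-rev["difference"], rel=1e-12)
        assert fwd["p_value"] == pytest.approx(rev["p_value"], rel=1e-9)

    def test_null_type_one_error_calibrated(self):
        """On a no-effect generator, Tukey-adjusted pairwise rejections occur
        for about 5% of replicates (familywise)."""
        null_means = {20.0: -12.0, 120.0: -12.0, 300.0: -12.0}
        hits = 0
        n_rep = 400
        for seed in range(n_rep):
            df = sample_peak_table(condition_means=null_means, seed=seed)
            fit = fit_condition_model(df["value"], df["condition"], df["subject"])
            ct = pairwise_contrasts(fit)
            hits += (ct["p_value"] < 0.05).any()
        assert 0.02 <= hits / n_rep <= 0.09

    def test_unadjusted_p_less_than_tukey(self):
        df = sample_peak_table(seed=13)
        fit = fit_condition_model(df["value"], df["condition"], df["subject"])
        tk = pairwise_contrasts(fit, adjust="tukey")
        un = pairwise_contrasts(fit, adjust="none")
        assert (un["p_value"] <= tk["p_value"] + 1e-12).all()


def _simulated_ratings(n_subjects=8, seed=0, b_exit=-2.0):
    """Cohort of ordinal ratings from the latent generator."""
    rng = np.random.default_rng(seed)
    vp = VertigoParams(b_exit=b_exit)
    peaks = {20.0: (-15.5, 5.4), 120.0: (-12.9, 4.0), 300.0: (-9.0, 2.2)}
    rows = []
    for s in range(n_subjects):
        subj = SubjectParams(gain=1.0, bias=0.0, ecc_limit=5.0, noise_sd=0.0,
                             vertigo_offset=float(rng.normal(0, 1.0)))
        for cond, (per, post) in peaks.items():
            for phase, pk in (("entry", per), ("exit", post)):
                cat, _, _ = synth_vertigo(pk, phase, subj, rng, vp)
                rows.append((cat, cond, phase, f"S{s}"))
    r, c, p, s = zip(*rows)
    return list(r), list(c), list(p), list(s)


class TestOrdinalModel:
    def test_phase_effect_sign_recovered(self):
        signs = []
        for seed in range(6):
            r, c, p, s = _simulated_ratings(seed=seed)
            fit = fit_ordinal_intensity(r, c, p, s)
            signs.append(fit.coef["phase[exit]"] < 0)
        assert all(signs)

    def test_condition_ordering_recovered(self):
        r, c, p, s = _simulated_ratings(seed=3)
        fit = fit_ordinal_intensity(r, c, p, s)
        # against the 20-s reference, longer durations have lower latent
        # intensity, monotonically
        assert fit.coef["condition[300]"] < fit.coef["condition[120]"] < 0

    def test_cutpoints_increasing_and_probs_sum_to_one(self):
        r, c, p, s = _simulated_ratings(seed=1)
        fit = fit_ordinal_intensity(r, c, p, s)
        assert np.all(np.diff(fit.cutpoints) > 0)
        probs = fit.category_probs({"condition[120]": 1.0})
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(probs >= 0)

    def test_single_category_triggers_penalized_path(self):
        r = ["none"] * 12
        c = [20.0, 120.0, 300.0] * 4
        p = ["entry", "exit"] * 6
        s = [f"S{i//6}" for i in range(12)]
        with pytest.warns(RuntimeWarning, match="separation|degenerate"):
            fit = fit_ordinal_intensity(r, c, p, s)
        assert fit.penalized


class TestDurationRegression:
    def test_collinear_points_perfect_fit(self):
        res = duration_regression([0, 100, 200, 300], [16.0, 14.0, 12.0, 10.0])
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-0.02, abs=1e-12)  # magnitude slope

    def test_constant_peaks_zero_r2(self):
        res = duration_regression([0, 100, 200], [5.0, 5.0, 5.0])
        assert res.r2 == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            duration_regression([0, 100], [5.0, 4.0])

    def test_magnitudes_used_not_signs(self):
        res_neg = duration_regression([0, 100, 200], [-16.0, -12.0, -8.0])
        res_pos = duration_regression([0, 100, 200], [16.0, 12.0, 8.0])
        assert res_neg.slope == pytest.approx(res_pos.slope)
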