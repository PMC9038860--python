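"""Regression, diagnostics, ROC/Youden, power, ICC and reader consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from vnca_marrow.inference import (
    DecisionRule,
    PowerSpec,
    breusch_pagan,
    confusion_metrics,
    fit_infiltration_model,
    icc2,
    logit_bounded,
    majority_vote,
    binarize_diagnosis,
    regression_sample_size,
    roc_power,
    roc_youden,
    white_hc0,
)


def synthetic_cohort(n: int, slope: float, seed: int) -> pd.DataFrame:
    """Cohort whose latent logit-scale infiltration follows a known slope."""
    r = np.random.default_rng(seed)
    x1 = r.normal(0.0, 1.0, n)
    x2 = r.normal(0.0, 1.0, n)
    latent = slope * x1 + r.normal(0.0, 1.0, n)
    y = np.clip((expit(latent) * n - 0.5) / (n - 1), 0.0, 1.0)
    return pd.DataFrame({"infiltration": y, "non_fatty_percent": x1, "bmd_mg_ml": x2})


class TestLogitBounded:
    def test_symmetry_and_midpoint(self):
        assert logit_bounded(0.5, 35) == pytest.approx(0.0)
        assert logit_bounded(0.0, 35) == pytest.approx(-logit_bounded(1.0, 35))

    def test_boundary_closed_form(self):
        # (0 * 34 + 0.5)/35 = 1/70 -> log(1/69)
        assert logit_bounded(0.0, 35) == pytest.approx(np.log(1 / 69), abs=1e-10)
        assert logit_bounded(0.0, 35) == pytest.approx(-4.2341, abs=5e-5)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            logit_bounded(0.5, 1)
        with pytest.raises(ValueError):
            logit_bounded(1.2, 35)


class TestRegression:
    def test_slope_recovery(self):
        res = fit_infiltration_model(synthetic_cohort(200, 0.8, seed=42))
        assert res.params["non_fatty_percent"] == pytest.approx(0.8, abs=0.15)

    def test_duplicated_predictor_is_rank_deficient(self):
        t = synthetic_cohort(50, 0.5, seed=1)
        t["bmd_mg_ml"] = t["non_fatty_percent"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_infiltration_model(t)

    def test_too_few_cases(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_infiltration_model(synthetic_cohort(8, 0.5, seed=1))

    def test_vif_floor_and_diagnostics_present(self):
        res = fit_infiltration_model(synthetic_cohort(100, 0.5, seed=3))
        assert all(v >= 1.0 for v in res.vif.values())
        assert 0.0 <= res.bp_p <= 1.0
        assert -1.0 <= res.partial_r <= 1.0

    def test_reported_se_matches_hand_hc1_sandwich(self):
        """The robust SEs are the df-corrected White sandwich, recomputed long-hand."""
        t = synthetic_cohort(40, 0.6, seed=5)
        res = fit_infiltration_model(t)
        y = logit_bounded(t["infiltration"].to_numpy(), 40)
        X = np.column_stack(
            [np.ones(40), t["non_fatty_percent"], t["bmd_mg_ml"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ beta
        n, k = X.shape
        cov = white_hc0(X, e) * n / (n - k)
        np.testing.assert_allclose(
            [res.robust_se["const"], res.robust_se["non_fatty_percent"], res.robust_se["bmd_mg_ml"]],
            np.sqrt(np.diag(cov)),
            rtol=1e-10,
        )


class TestBreuschPagan:
    def test_four_point_hand_statistic(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        e = np.array([1.0, -1.0, 2.0, -2.0])
        stat, p = breusch_pagan(X, e)
        # long-hand auxiliary regression of e^2 on X
        e2 = e**2
        beta = np.linalg.lstsq(X, e2, rcond=None)[0]
        ss_res = np.sum((e2 - X @ beta) ** 2)
        ss_tot = np.sum((e2 - e2.mean()) ** 2)
        expected = 4 * (1 - ss_res / ss_tot)
        assert stat == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import het_breuschpagan

        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        e = rng.normal(size=80) * (1 + 0.5 * np.abs(X[:, 1]))
        stat, p = breusch_pagan(X, e)
        sm_stat, sm_p, _, _ = het_breuschpagan(e, X)
        assert stat == pytest.approx(sm_stat, rel=1e-10)
        assert p == pytest.approx(sm_p, rel=1e-10)

    def test_constant_residuals(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        assert breusch_pagan(X, np.ones(10)) == (0.0, 1.0)

    def test_size_and_power(self):
        """Nominal size under homoskedasticity; high power when var grows with x."""
        reps, n = 600, 300
        rej_null = rej_het = 0
        for s in range(reps):
            r = np.random.default_rng(s)
            x = r.uniform(0.5, 3.0, n)
            X = np.column_stack([np.ones(n), x])
            rej_null += breusch_pagan(X, r.normal(0, 1, n))[1] < 0.05
            rej_het += breusch_pagan(X, r.normal(0, 1, n) * np.sqrt(x))[1] < 0.05
        assert 0.02 <= rej_null / reps <= 0.08
        assert rej_het / reps > 0.9


def youden_oracle(scores, labels):
    """Exhaustive enumeration over all midpoint thresholds."""
    u = np.unique(scores)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    best = None
    for thr in candidates:
        called = scores > thr
        sens = called[labels == 1].mean()
        spec = (~called)[labels == 0].mean()
        j = sens + spec - 1.0
        if best is None or j >= best[0]:
            best = (j, thr, sens, spec)
    return best


class TestROC:
    def test_perfect_separation(self):
        res = roc_youden(np.array([1, 2, 3, 10, 11, 12.0]), np.array([0, 0, 0, 1, 1, 1]))
        assert res.auc == 1.0 and res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3 < res.youden_threshold < 10

    def test_uninformative_scores(self):
        res = roc_youden(np.full(10, 2.0), np.array([0, 1] * 5), compute_power=False)
        assert res.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_youden(np.arange(4.0), np.ones(4, dtype=int))

    def test_eight_point_hand_set_matches_enumeration(self):
        scores = np.array([0.1, 0.2, 0.35, 0.4, 0.55, 0.6, 0.8, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        res = roc_youden(scores, labels, compute_power=False)
        j, thr, sens, spec = youden_oracle(scores, labels)
        assert res.youden_threshold == thr
        assert res.sensitivity == sens and res.specificity == spec
        # empirical AUC by direct pair counting
        x, y = scores[labels == 1], scores[labels == 0]
        pairs = (x[:, None] > y[None, :]).mean()
        assert res.auc == pytest.approx(pairs)

    def test_ci_contains_auc_and_is_bounded(self, rng):
        scores = rng.normal(0, 1, 60) + np.repeat([0.0, 1.0], 30)
        labels = np.repeat([0, 1], 30)
        res = roc_youden(scores, labels, compute_power=False)
        lo, hi = res.ci95
        assert 0.0 <= lo <= res.auc <= hi <= 1.0


class TestConfusion:
    @pytest.mark.parametrize(
        "tp, fn, tn, fp, sens, spec",
        [
            (11, 2, 13, 9, 0.85, 0.59),
            (5, 3, 10, 4, 0.63, 0.71),
        ],
    )
    def test_reported_reader_counts(self, tp, fn, tn, fp, sens, spec):
        m = confusion_metrics(tp, fn, tn, fp)
        assert m.rounded() == (sens, spec)
        assert m.sensitivity_fraction == (tp, tp + fn)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            confusion_metrics(0, 0, 5, 5)


class TestROCPower:
    def test_null_boundary_equals_alpha(self):
        assert roc_power(0.5, 13, 22, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_auc_and_sizes(self):
        aucs = [0.55, 0.6, 0.7, 0.8, 0.9, 0.99]
        powers = [roc_power(a, 13, 22) for a in aucs]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert roc_power(0.7, 26, 22) > roc_power(0.7, 13, 22)
        assert roc_power(0.7, 13, 44) > roc_power(0.7, 13, 22)
        assert roc_power(0.999999, 13, 22) > 0.999

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            roc_power(0.4, 13, 22)
        with pytest.raises(ValueError):
            roc_power(0.7, 1, 22)


class TestSampleSize:
    def test_monotone_in_effect_size(self):
        base = regression_sample_size(PowerSpec(f2=0.32))
        assert regression_sample_size(PowerSpec(f2=0.64)) <= base
        assert regression_sample_size(PowerSpec(f2=0.16)) > base

    def test_huge_effect_approaches_minimum(self):
        assert regression_sample_size(PowerSpec(f2=1000.0)) <= PowerSpec().n_predictors + 3

    def test_monte_carlo_power_at_returned_n(self):
        """Simulated rejection rate at the planned n matches the target power.

        Fixed design with the main predictor standardised to unit sample
        variance, so the noncentrality is exactly f^2 * n as in the planning
        formula; only the noise is redrawn.
        """
        ps = PowerSpec(f2=0.32, alpha=0.05, power=0.8, n_predictors=2)
        n = regression_sample_size(ps)
        b = np.sqrt(ps.f2)  # f^2 = b^2 with unit-variance predictor and noise
        design_rng = np.random.default_rng(99)
        x1 = design_rng.normal(size=n)
        x1 = (x1 - x1.mean()) / x1.std()
        x2 = design_rng.normal(size=n)
        x2 = x2 - np.polyval(np.polyfit(x1, x2, 1), x1)  # orthogonal to x1
        X = np.column_stack([np.ones(n), x1, x2])
        rej = 0
        reps = 800
        for s in range(reps):
            r = np.random.default_rng(s)
            y = b * X[:, 1] + r.normal(size=n)
            beta, ss_res, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - 3)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            pval = 2 * stats.t.sf(abs(beta[1] / se), n - 3)
            rej += pval < ps.alpha
        assert rej / reps == pytest.approx(0.8, abs=0.06)


class TestICC:
    def test_identical_raters(self):
        ratings = np.tile(np.arange(10.0)[:, None], (1, 2))
        assert icc2(ratings) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        assert abs(icc2(rng.normal(size=(200, 2)))) < 0.15

    def test_six_by_two_hand_anova(self):
        ratings = np.array(
            [[9.0, 2.0], [8.0, 1.0], [7.0, 4.0], [10.0, 5.0], [6.0, 2.0], [5.0, 1.0]]
        )
        n, k = ratings.shape
        grand = ratings.mean()
        msr = k * ((ratings.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((ratings.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((ratings - grand) ** 2).sum()
            - (n - 1) * msr
            - (k - 1) * msc
        ) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc2(ratings) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(11)
        subject_effect = rng.normal(0, 2, 12)
        ratings = subject_effect[:, None] + rng.normal(0, 1, (12, 3)) + [0.0, 0.5, -0.3]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": ratings.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subject", "rater", "score")
        # ICC(A,1): two-way random effects, absolute agreement, single rater
        ref_icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].item()
        assert icc2(ratings) == pytest.approx(ref_icc2, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            icc2(np.ones((5, 2)))
        with pytest.raises(ValueError):
            icc2(np.zeros((2, 2)))


class TestVotesAndRules:
    @pytest.mark.parametrize("calls, out", [((1, 1, 0), 1), ((0, 0, 0), 0), ((1, 0, 0), 0)])
    def test_majority(self, calls, out):
        assert majority_vote(calls) == out

    def test_vote_arity(self):
        with pytest.raises(ValueError):
            majority_vote((1, 0))

    def test_decision_rule_is_strict(self):
        rule = DecisionRule(0.93)
        assert list(rule(np.array([0.93, 0.931, 0.0]))) == [0, 1, 0]

    @pytest.mark.parametrize(
        "group, infil, out",
        [("MM", 0.0, 1), ("MGUS", 0.0, 0), ("SMM", 0.12, 1), ("SMM", 0.05, 0)],
    )
    def test_smm_merge_rule(self, group, infil, out):
        assert binarize_diagnosis(group, infil) == out
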