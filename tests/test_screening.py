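"""Group tests, logistic regression, ROC/Youden/DeLong, score combination."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest

from airwaymorph.errors import NoVarianceError, SingleClassError
from airwaymorph.screening import (
    auc_mann_whitney,
    calibrate_intercept,
    combine_scores,
    compare_groups,
    crude_or_roundtrip,
    fit_logistic,
    roc_analysis,
)


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        x = [1.0, 1.0, 2.0, 2.0, 3.0]
        res = compare_groups(x, list(x))
        assert res.p_value == pytest.approx(1.0)

    def test_separated_normals_use_t(self):
        rng = np.random.default_rng(30)
        res = compare_groups(rng.normal(0, 1, 42), rng.normal(5, 1, 42))
        assert res.test == "t"
        assert res.p_value < 1e-10

    def test_mann_whitney_statistic_matches_pair_enumeration(self):
        # a heavy outlier defeats the normality gate -> Mann-Whitney branch
        x = [1.2, 3.4, 2.2, 50.0, 2.9]
        y = [2.0, 1.1, 4.0, 3.3, 2.2]
        res = compare_groups(x, y)
        assert res.test == "mann_whitney"
        u_oracle = sum((1.0 if xi > yi else 0.5 if xi == yi else 0.0)
                       for xi in x for yi in y)
        assert res.statistic == pytest.approx(u_oracle)

    def test_summaries_match_raw_data(self):
        rng = np.random.default_rng(31)
        x, y = rng.normal(10, 2, 20), rng.normal(12, 2, 25)
        res = compare_groups(x, y, groups=("g1", "g2"))
        assert res.summaries["g1"]["mean"] == pytest.approx(np.mean(x))
        assert res.summaries["g2"]["median"] == pytest.approx(np.median(y))
        assert res.summaries["g1"]["sd"] == pytest.approx(np.std(x, ddof=1))


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        # cells: exposed cases 20, exposed non-cases 10,
        #        unexposed cases 10, unexposed non-cases 20 -> OR = 4
        x = np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.odds_ratio["x"] == pytest.approx(4.0, abs=1e-6)
        assert fit.ci_low["x"] < 4.0 < fit.ci_high["x"]

    def test_likelihood_beats_grid_oracle(self):
        rng = np.random.default_rng(32)
        x = rng.normal(0, 1, 60)
        y = (rng.random(60) < expit(-0.5 + 1.2 * x)).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        b0g, b1g = np.meshgrid(np.linspace(-3, 3, 200),
                               np.linspace(-3, 3, 200), indexing="ij")
        eta = b0g[..., None] + b1g[..., None] * x
        ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)
        assert fit.log_likelihood >= ll.max() - 1e-9

    def test_constant_outcome_rejected(self):
        with pytest.raises(NoVarianceError):
            fit_logistic(np.zeros(20), pd.DataFrame({"x": np.arange(20.0)}))

    def test_constant_predictor_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(NoVarianceError):
            fit_logistic(y, pd.DataFrame({"x": np.ones(20)}))

    def test_adjusted_fit_reports_all_predictors(self):
        rng = np.random.default_rng(33)
        n = 80
        x = rng.normal(70, 8, n)
        age = rng.uniform(4, 200, n)
        sex = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < expit(-8 + 0.1 * x)).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"ipa": x}),
                           adjust=pd.DataFrame({"age": age, "sex": sex}))
        assert set(fit.odds_ratio) == {"ipa", "age", "sex"}
        assert fit.adjusted_for == ("age", "sex")
        for k in fit.odds_ratio:
            assert fit.ci_low[k] < fit.odds_ratio[k] < fit.ci_high[k]

    def test_wald_p_uniform_under_null(self):
        """Crude logistic p values are ~uniform with uninformative scores."""
        rng = np.random.default_rng(34)
        pvals = []
        while len(pvals) < 500:
            y = (rng.random(84) < 10 / 84).astype(int)
            x = rng.normal(0, 1, 84)
            if y.sum() in (0, 84):
                continue
            pvals.append(fit_logistic(y, pd.DataFrame({"x": x})).p_value["x"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        roc = roc_analysis(scores, labels)
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_eight_point_brute_force_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.55, 0.2, 0.7, 0.45])
        labels = np.array([0, 0, 1, 1, 1, 0, 1, 0])
        roc = roc_analysis(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        auc_oracle = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                              for p in pos for q in neg])
        assert roc.auc == pytest.approx(auc_oracle, abs=1e-12)
        # exhaustive threshold scan over score midpoints
        uniq = np.unique(scores)
        thr = (uniq[:-1] + uniq[1:]) / 2
        best_j, best_t = -np.inf, None
        for t in thr:
            j = (pos >= t).mean() + (neg < t).mean() - 1.0
            if j > best_j:
                best_j, best_t = j, t
        assert roc.cutoff == pytest.approx(best_t)
        assert (roc.sensitivity + roc.specificity - 1.0
                ) == pytest.approx(best_j, abs=1e-12)

    def test_null_auc_centered_at_half(self):
        rng = np.random.default_rng(35)
        scores = rng.normal(0, 1, 84)
        aucs = []
        for _ in range(1000):
            labels = np.zeros(84, int)
            labels[rng.choice(84, 10, replace=False)] = 1
            aucs.append(auc_mann_whitney(scores, labels))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(36)
        scores = rng.normal(0, 1, 60)
        labels = (rng.random(60) < expit(scores)).astype(int)
        a1 = roc_analysis(scores, labels).auc
        a2 = roc_analysis(np.exp(3 * scores) + 7, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_orientation_flip_reported(self):
        rng = np.random.default_rng(37)
        scores = rng.normal(0, 1, 100)
        labels = (rng.random(100) < expit(-2.0 * scores)).astype(int)
        roc = roc_analysis(scores, labels)
        assert roc.flipped and roc.direction == "less"
        assert roc.auc > 0.5
        # cutoff reported on the original scale: score <= cutoff is positive
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        assert roc.sensitivity == pytest.approx((pos <= roc.cutoff).mean())
        assert roc.specificity == pytest.approx((neg > roc.cutoff).mean())

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(38)
        scores = rng.normal(0, 1, 84)
        labels = (rng.random(84) < expit(1.5 * scores - 1)).astype(int)
        roc = roc_analysis(scores, labels)
        assert roc.ci_low <= roc.auc <= roc.ci_high
        assert 0.0 <= roc.ci_low and roc.ci_high <= 1.0

    def test_auc_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(39)
        scores = rng.normal(0, 1, 200)
        labels = (rng.random(200) < expit(scores)).astype(int)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_analysis([1.0, 2.0, 3.0], [1, 1, 1])


class TestCombineScores:
    def test_redundant_second_score_changes_nothing(self):
        rng = np.random.default_rng(40)
        s = rng.normal(0, 1, 84)
        labels = (rng.random(84) < expit(1.5 * s)).astype(int)
        single = roc_analysis(s, labels).auc
        combined = combine_scores(pd.DataFrame({"a": s, "b": s}), labels).auc
        assert combined == pytest.approx(single, abs=1e-9)

    def test_two_informative_scores_do_not_hurt(self):
        rng = np.random.default_rng(41)
        worse = 0
        for _ in range(100):
            a = rng.normal(0, 1, 120)
            b = rng.normal(0, 1, 120)
            labels = (rng.random(120) < expit(1.0 * a + 1.0 * b)).astype(int)
            if labels.min() == labels.max():
                continue
            best_single = max(roc_analysis(a, labels).auc,
                              roc_analysis(b, labels).auc)
            combo = combine_scores(pd.DataFrame({"a": a, "b": b}), labels).auc
            if combo < best_single - 0.02:
                worse += 1
        assert worse <= 5

    def test_pure_noise_second_score_no_inflation(self):
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(50):
            a = rng.normal(0, 1, 84)
            noise = rng.normal(0, 1, 84)
            labels = (rng.random(84) < expit(2.0 * a)).astype(int)
            if labels.min() == labels.max():
                continue
            single = roc_analysis(a, labels).auc
            combo = combine_scores(pd.DataFrame({"a": a, "n": noise}),
                                   labels).auc
            diffs.append(combo - single)
        assert abs(np.mean(diffs)) < 0.03


class TestRoundTrip:
    def test_calibrated_intercept_hits_prevalence(self):
        b0 = calibrate_intercept(78.6, 9.6, 69.0, 4.8, np.log(1.11), 0.12)
        rng = np.random.default_rng(43)
        x = np.r_[rng.normal(78.6, 9.6, 50000), rng.normal(69.0, 4.8, 50000)]
        prev = expit(b0 + np.log(1.11) * x).mean()
        assert prev == pytest.approx(0.12, abs=0.003)

    def test_recovers_generating_odds_ratio(self):
        res = crude_or_roundtrip(78.6, 9.6, 69.0, 4.8, true_or=1.11,
                                 n=840, n_seeds=10, seed=5)
        assert res["mean_or"] == pytest.approx(1.11, abs=0.03)
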