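"""Metrics, fold summaries, bootstrap CIs and DeLong's test."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from pcrfusion.evaluation import (
    auc_score,
    bootstrap_ci,
    confusion_and_metrics,
    delong_test,
    fold_summary,
)

from _oracles import auc_pair_counting, delong_slow

# Five cross-validation folds of a 31-patient test split (9 responders,
# 22 non-responders): confusion counts and the metric values they imply.
FOLD_CASES = [
    # (tp, fn, tn, fp, ACC, PPV, NPV, SEN, SPE, F1)
    (9, 0, 20, 2, 0.9355, 0.8182, 1.0, 1.0, 0.9091, 0.9),
    (7, 2, 20, 2, 0.8710, 0.7778, 0.9091, 0.7778, 0.9091, 0.7778),
    (4, 5, 19, 3, 0.7419, 0.5714, 0.7917, 0.4444, 0.8636, 0.5),
    (7, 2, 16, 6, 0.7419, 0.5385, 0.8889, 0.7778, 0.7273, 0.6364),
    (8, 1, 21, 1, 0.9355, 0.8889, 0.9545, 0.8889, 0.9545, 0.8889),
]

FOLD_AUCS = [0.9545, 0.8838, 0.7172, 0.7677, 0.9141]


def labels_preds_from_counts(tp, fn, tn, fp):
    labels = np.array([1] * (tp + fn) + [0] * (tn + fp))
    preds = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
    return labels, preds


class TestConfusionMetrics:
    @pytest.mark.parametrize("tp,fn,tn,fp,acc,ppv,npv,sen,spe,f1", FOLD_CASES)
    def test_fold_confusion_arithmetic(self, tp, fn, tn, fp, acc, ppv, npv,
                                       sen, spe, f1):
        labels, preds = labels_preds_from_counts(tp, fn, tn, fp)
        counts, report = confusion_and_metrics(labels, preds)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (tp, fn, tn, fp)
        assert round(report["ACC"], 4) == acc
        assert round(report["PPV"], 4) == ppv
        assert round(report["NPV"], 4) == npv
        assert round(report["SEN"], 4) == sen
        assert round(report["SPE"], 4) == spe
        assert round(report["F1"], 4) == f1

    def test_all_correct_gives_ones(self):
        _, report = confusion_and_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert all(v == 1.0 for v in report.values.values())

    def test_zero_denominator_flagged_not_zeroed(self):
        # no predicted positives: PPV undefined
        _, report = confusion_and_metrics([1, 0, 0], [0, 0, 0])
        assert "PPV" in report.undefined
        assert np.isnan(report["PPV"])

    def test_accuracy_identity_on_random_inputs(self, rng):
        labels = rng.integers(0, 2, 50)
        preds = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        _, r = confusion_and_metrics(labels, preds)
        p, n = labels.sum(), (labels == 0).sum()
        assert r["ACC"] == pytest.approx((r["SEN"] * p + r["SPE"] * n) / (p + n))

    def test_f1_equivalent_form(self, rng):
        labels = rng.integers(0, 2, 40)
        preds = rng.integers(0, 2, 40)
        counts, r = confusion_and_metrics(labels, preds)
        if not np.isnan(r["F1"]):
            assert r["F1"] == pytest.approx(
                2 * counts.tp / (2 * counts.tp + counts.fp + counts.fn)
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([], [])


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc_score([0, 1, 0, 1], np.ones(4)) == 0.5

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 12)
        if labels.sum() in (0, 12):
            labels[0] = 1 - labels[0]
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], 12)  # ties included
        ours = auc_score(labels, scores)
        assert ours == pytest.approx(auc_pair_counting(labels, scores), abs=1e-9)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.normal(size=30)
        assert auc_score(labels, scores) == pytest.approx(
            auc_score(labels, np.exp(3 * scores) + 7)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([1, 1, 1], [0.2, 0.4, 0.6])


class TestFoldSummary:
    def test_mean_and_population_sd_of_fold_aucs(self):
        out = fold_summary(FOLD_AUCS)
        assert round(out["mean"], 4) == 0.8475
        assert round(out["sd"], 4) == 0.0901

    def test_t_confidence_interval(self):
        out = fold_summary(FOLD_AUCS)
        assert out["ci_lower"] == pytest.approx(0.7356, abs=5e-4)
        assert out["ci_upper"] == pytest.approx(0.9594, abs=5e-4)

    def test_sample_convention_flag(self):
        out = fold_summary(FOLD_AUCS, ddof=1)
        assert out["sd"] == pytest.approx(np.std(FOLD_AUCS, ddof=1))
        assert round(out["sd"], 4) != 0.0901

    def test_fewer_than_two_folds_rejected(self):
        with pytest.raises(ValueError):
            fold_summary([0.8])


class TestBootstrap:
    def test_constant_metric_gives_zero_width(self):
        labels = np.array([0, 1] * 10)
        lo, hi, _ = bootstrap_ci(labels, labels.astype(float),
                                 lambda y, s: 1.0, n_boot=50, seed=0)
        assert lo == hi == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_interval_brackets_point_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 60)
        scores = np.clip(labels + rng.normal(0, 0.8, 60), 0, 1)

        def acc(y, s):
            from pcrfusion.evaluation import confusion_and_metrics as cm

            return cm(y, (s >= 0.5).astype(int))[1]["ACC"]

        point = acc(labels, scores)
        lo, hi, _ = bootstrap_ci(labels, scores, acc, n_boot=200, seed=seed)
        assert lo <= point <= hi

    def test_metric_undefined_on_full_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1, 1, 1], [0.5, 0.5, 0.5], auc_score, n_boot=10, seed=0)

    def test_undefined_resamples_are_redrawn(self):
        # one lone negative: many resamples miss it and AUC is undefined
        labels = np.array([1] * 9 + [0])
        scores = np.linspace(0, 1, 10)
        lo, hi, redraws = bootstrap_ci(labels, scores, auc_score,
                                       n_boot=100, seed=1)
        assert redraws > 0
        assert 0.0 <= lo <= hi <= 1.0


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        scores = rng.normal(size=20)
        diff, p = delong_test(labels, scores, scores)
        assert diff == 0.0 and p == 1.0

    def test_antisymmetric_difference_same_p(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a, b = rng.normal(size=(2, 30))
        d1, p1 = delong_test(labels, a, b)
        d2, p2 = delong_test(labels, b, a)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        a = rng.normal(size=40)
        b = 0.5 * a + rng.normal(size=40)  # correlated scores
        diff, p = delong_test(labels, a, b)
        diff_ref, p_ref = delong_slow(labels, a, b)
        assert diff == pytest.approx(diff_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_discriminating_scores_reach_significance(self, rng):
        labels = np.array([0, 1] * 50)
        good = labels + rng.normal(0, 0.3, 100)
        noise = rng.normal(size=100)
        _, p = delong_test(labels, good, noise)
        assert p < 0.01
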