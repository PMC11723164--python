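"""LPSO splitting, weighted metrics and the validation loop."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from adrisk import (
    FeatureMatrix,
    LeavePSubjectsOut,
    aggregate_confusion,
    make_lpso_plan,
    make_trials_meta,
    run_validation,
    significance_vs_chance,
    trapezoid_auc,
    weighted_metrics,
)
from adrisk.evaluation import ConfusionMatrix, confusion_from_labels, default_classifiers


def cohort(n_neutral=21, n_risky=18):
    subs = [f"N{i:02d}" for i in range(n_neutral)] + [
        f"R{i:02d}" for i in range(n_risky)
    ]
    groups = ["neutral"] * n_neutral + ["risky"] * n_risky
    return pd.Series(groups, index=subs, name="group")


def trial_fm(rng, n_neutral=21, n_risky=18, trials=12, n_features=9, shift=0.0):
    rows, X = [], []
    for s, g in cohort(n_neutral, n_risky).items():
        for _ in range(trials):
            rows.append((s, g, "SH", 800.0, True))
            X.append(
                rng.standard_normal(n_features)
                + (shift if g == "risky" else 0.0)
            )
    meta = pd.DataFrame(
        rows, columns=["subject_id", "group", "condition", "response_time", "correct"]
    )
    return FeatureMatrix(
        np.asarray(X), [f"f{i}" for i in range(n_features)], "custom", meta
    )


def mann_whitney_auc(y_true, scores):
    """Pair-counting AUC: concordant + half-ties over all pos/neg pairs."""
    pos = scores[np.asarray(y_true, dtype=bool)]
    neg = scores[~np.asarray(y_true, dtype=bool)]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestSplitPlan:
    def test_train_test_sizes(self):
        plan = make_lpso_plan(cohort(), n_iterations=5)
        groups = cohort()
        for test, train in zip(plan.test_subjects, plan.train_subjects):
            assert sum(groups[s] == "neutral" for s in test) == 5
            assert sum(groups[s] == "risky" for s in test) == 4
            assert sum(groups[s] == "neutral" for s in train) == 16
            assert sum(groups[s] == "risky" for s in train) == 14

    def test_disjoint_and_reproducible(self):
        a = make_lpso_plan(cohort())
        b = make_lpso_plan(cohort())
        assert a == b
        assert a.seeds == tuple(range(42, 142))
        for test, train in zip(a.test_subjects, a.train_subjects):
            assert not set(test) & set(train)
            assert len(set(test) | set(train)) == 39

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="need"):
            make_lpso_plan(cohort(5, 4))

    def test_sklearn_splitter_interface(self, rng):
        fm = trial_fm(rng, trials=2)
        cv = LeavePSubjectsOut(n_iterations=3)
        subjects = fm.subject_ids
        y = fm.labels
        splits = list(cv.split(fm.values, y, subjects))
        assert len(splits) == cv.get_n_splits()
        for tr, te in splits:
            assert not set(subjects[tr]) & set(subjects[te])


class TestTrapezoidAuc:
    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = 50
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            assert trapezoid_auc(y, scores) == pytest.approx(
                mann_whitney_auc(y, scores), abs=1e-10
            )

    def test_matches_sklearn(self, rng):
        y = rng.random(200) < 0.5
        scores = rng.standard_normal(200)
        assert trapezoid_auc(y, scores) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )

    def test_perfect_separation(self):
        y = np.array([True] * 5 + [False] * 5)
        scores = np.array([2.0] * 5 + [1.0] * 5)
        assert trapezoid_auc(y, scores) == 1.0


class TestWeightedMetrics:
    def test_accuracy_arithmetic(self):
        # TP=3 FP=1 FN=2 TN=4
        y_true = ["risky"] * 5 + ["neutral"] * 5
        y_pred = ["risky"] * 3 + ["neutral"] * 2 + ["risky"] * 1 + ["neutral"] * 4
        m = weighted_metrics(
            np.array(y_true), np.array(y_pred), np.arange(10)[::-1].astype(float)
        )
        assert m["accuracy"] == pytest.approx(0.7)

    def test_perfect_scores_unit_auc(self):
        y_true = np.array(["risky"] * 4 + ["neutral"] * 6)
        scores = np.array([5, 4, 3.5, 3, 2, 1, 0.5, 0.2, 0.1, 0.0])
        m = weighted_metrics(y_true, np.where(scores > 2.5, "risky", "neutral"), scores)
        assert m["roc_auc"] == pytest.approx(1.0)

    def test_binary_weighted_auc_equals_positive_auc(self, rng):
        y_true = np.where(rng.random(100) < 0.4, "risky", "neutral")
        scores = rng.standard_normal(100)
        m = weighted_metrics(
            y_true, np.where(scores > 0, "risky", "neutral"), scores
        )
        assert m["roc_auc"] == pytest.approx(
            trapezoid_auc(y_true == "risky", scores), abs=1e-12
        )

    def test_matches_sklearn_weighted_prf(self, rng):
        y_true = np.where(rng.random(80) < 0.45, "risky", "neutral")
        y_pred = np.where(rng.random(80) < 0.5, "risky", "neutral")
        m = weighted_metrics(y_true, y_pred, rng.standard_normal(80))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
        assert m["precision"] == pytest.approx(p)
        assert m["recall"] == pytest.approx(r)
        assert m["f1"] == pytest.approx(f)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics(np.array([]), np.array([]), np.array([]))


class TestConfusionAggregation:
    def test_single_iteration_row_percentages(self):
        agg = aggregate_confusion([ConfusionMatrix(TP=6, FN=4, FP=2, TN=8)])
        assert np.allclose(agg, [[60.0, 40.0], [20.0, 80.0]])

    def test_identical_iterations_idempotent(self):
        c = ConfusionMatrix(TP=3, FN=1, FP=2, TN=6)
        assert np.allclose(aggregate_confusion([c] * 7), aggregate_confusion([c]))

    def test_random_matches_direct_mean(self, rng):
        confs = [
            ConfusionMatrix(*rng.integers(1, 20, 4).tolist()) for _ in range(10)
        ]
        agg = aggregate_confusion(confs)
        oracle = np.mean(
            [100 * c.as_array() / c.as_array().sum(1, keepdims=True) for c in confs],
            axis=0,
        )
        assert np.allclose(agg, oracle)
        assert np.allclose(agg.sum(axis=1), 100.0)


class TestSignificance:
    def test_zero_variance_conservative(self):
        p, stars = significance_vs_chance(np.full(100, 0.5))
        assert p == 1.0 and stars == ""

    def test_clear_effect_three_stars(self, rng):
        x = rng.normal(0.6, 0.01, 100)
        p, stars = significance_vs_chance(x)
        # analytic oracle: t = (mean-0.5)/(sd/sqrt(n)) is astronomically large
        from scipy import stats

        t = (x.mean() - 0.5) / (x.std(ddof=1) / np.sqrt(len(x)))
        assert p == pytest.approx(stats.t.sf(t, len(x) - 1), rel=1e-10)
        assert p < 1e-3 and stars == "***"

    def test_type_one_error_control(self, rng):
        rejections = 0
        for _ in range(40):
            x = rng.normal(0.5, 0.05, 100)
            p, _ = significance_vs_chance(x)
            rejections += p < 0.05
        assert rejections <= 6  # ~5% expected under the null

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            significance_vs_chance(np.array([0.6]))


class TestRunValidation:
    def test_pure_noise_is_chance_level(self, rng):
        # a single finite dataset has a dataset-conditional AUC offset, so
        # chance level is assessed over replicate noise datasets
        aucs = []
        for _ in range(5):
            fm = trial_fm(rng, trials=8)
            plan = make_lpso_plan(cohort(), n_iterations=20)
            report = run_validation(
                fm, plan, {"logreg": LogisticRegression(max_iter=200)}
            )
            aucs.append(report.mean_metrics.loc["logreg", "roc_auc"])
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_separable_feature_high_accuracy_all_models(self, rng):
        fm = trial_fm(rng, trials=6, n_features=1, shift=8.0)
        plan = make_lpso_plan(cohort(), n_iterations=8)
        report = run_validation(fm, plan, default_classifiers())
        assert (report.mean_metrics["accuracy"] > 0.9).all()
        assert (report.mean_metrics["roc_auc"] > 0.95).all()

    def test_reproducible(self, rng):
        fm = trial_fm(rng, trials=5, shift=0.4)
        plan = make_lpso_plan(cohort(), n_iterations=5)
        clf = {"logreg": LogisticRegression(max_iter=200)}
        a = run_validation(fm, plan, clf)
        b = run_validation(fm, plan, clf)
        pd.testing.assert_frame_equal(a.per_iteration, b.per_iteration)

    def test_confusion_rows_sum_to_hundred(self, rng):
        fm = trial_fm(rng, trials=5, shift=0.5)
        plan = make_lpso_plan(cohort(), n_iterations=5)
        report = run_validation(fm, plan, {"logreg": LogisticRegression(max_iter=200)})
        agg = report.confusion_pct["logreg"]
        assert np.allclose(agg.sum(axis=1), 100.0)
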