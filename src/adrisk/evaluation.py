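"""Cross-subject Leave-p%-Subjects-Out validation with weighted metrics.

Whole subjects are held out: each iteration draws a fixed test
composition (5 neutral + 4 risky subjects, ~20-25% of a 21+18 cohort)
with its own seed (defaults 42..141 over 100 iterations), trains each
classifier on the remaining subjects' trials and scores the held-out
trials.  Metrics are class-weighted (weights proportional to test-fold
class sizes): precision, recall, F1 and trapezoidal ROC AUC computed
with each class treated as positive in turn, plus plain accuracy.
Per-iteration confusion matrices are row-normalised to percentages and
averaged; each metric series is tested against chance (one-sample,
one-tailed t-test of mean > 0.5) with star coding at 0.05 / 0.01 / 0.001.

The positive class is ``risky`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import BaseCrossValidator
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

POSITIVE = "risky"
NEGATIVE = "neutral"

METRICS = ("accuracy", "precision", "recall", "f1", "roc_auc")

STAR_LEVELS = ((1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def default_classifiers(random_state: int = 0) -> dict[str, object]:
    """The four reference models with library-default hyperparameters."""
    return {
        "logreg": LogisticRegression(max_iter=1000, random_state=random_state),
        "rf": RandomForestClassifier(random_state=random_state),
        "svm": SVC(random_state=random_state),  # decision_function scores for AUC
        "gb": GradientBoostingClassifier(random_state=random_state),
    }


# --------------------------------------------------------------- split plan


@dataclass(frozen=True)
class SplitPlan:
    """Per-iteration train/test subject assignments."""

    seeds: tuple[int, ...]
    test_subjects: tuple[tuple[str, ...], ...]
    train_subjects: tuple[tuple[str, ...], ...]
    n_test_neutral: int
    n_test_risky: int

    @property
    def n_iterations(self) -> int:
        return len(self.seeds)


class LeavePSubjectsOut(BaseCrossValidator):
    """sklearn-compatible cross-validator holding out whole subjects.

    Each split draws ``n_test_neutral`` + ``n_test_risky`` subjects
    (without replacement within an iteration; iterations redraw
    independently) using one seed per iteration, so splits are
    bit-reproducible.  ``split`` requires ``groups`` = per-sample subject
    IDs and ``y`` = per-sample group labels.
    """

    def __init__(self, n_test_neutral: int = 5, n_test_risky: int = 4,
                 n_iterations: int = 100, seed_start: int = 42):
        self.n_test_neutral = n_test_neutral
        self.n_test_risky = n_test_risky
        self.n_iterations = n_iterations
        self.seed_start = seed_start

    @property
    def seeds(self) -> tuple[int, ...]:
        return tuple(range(self.seed_start, self.seed_start + self.n_iterations))

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_iterations

    def _iter_test_masks(self, X=None, y=None, groups=None):
        plan = self.plan(_subject_table(y, groups))
        groups = np.asarray(groups)
        for test in plan.test_subjects:
            yield np.isin(groups, test)

    def split(self, X, y=None, groups=None):
        if y is None or groups is None:
            raise ValueError("y (group labels) and groups (subject IDs) required")
        indices = np.arange(len(groups))
        for mask in self._iter_test_masks(X, y, groups):
            yield indices[~mask], indices[mask]

    def plan(self, subject_groups: pd.Series) -> SplitPlan:
        """Materialise the full plan from a subject_id -> group mapping."""
        neutral = np.asarray(
            sorted(subject_groups.index[subject_groups == NEGATIVE])
        )
        risky = np.asarray(sorted(subject_groups.index[subject_groups == POSITIVE]))
        if len(neutral) < self.n_test_neutral + 1 or len(risky) < self.n_test_risky + 1:
            raise ValueError(
                f"need > ({self.n_test_neutral} neutral, {self.n_test_risky} risky) "
                f"subjects, got ({len(neutral)}, {len(risky)})"
            )
        tests, trains = [], []
        for seed in self.seeds:
            rng = np.random.RandomState(seed)
            t_n = rng.choice(neutral, self.n_test_neutral, replace=False)
            t_r = rng.choice(risky, self.n_test_risky, replace=False)
            test = tuple(sorted(np.concatenate([t_n, t_r]).tolist()))
            train = tuple(
                sorted(set(neutral.tolist() + risky.tolist()) - set(test))
            )
            tests.append(test)
            trains.append(train)
        return SplitPlan(
            seeds=self.seeds,
            test_subjects=tuple(tests),
            train_subjects=tuple(trains),
            n_test_neutral=self.n_test_neutral,
            n_test_risky=self.n_test_risky,
        )


def _subject_table(y, groups) -> pd.Series:
    df = pd.DataFrame({"subject": np.asarray(groups), "group": np.asarray(y)})
    return df.groupby("subject")["group"].first()


def make_lpso_plan(
    subject_groups: pd.Series,
    n_test_neutral: int = 5,
    n_test_risky: int = 4,
    n_iterations: int = 100,
    seed_start: int = 42,
) -> SplitPlan:
    """Deterministic LPSO plan from a subject_id -> group mapping."""
    return LeavePSubjectsOut(
        n_test_neutral, n_test_risky, n_iterations, seed_start
    ).plan(subject_groups)


# ------------------------------------------------------------------ metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Trial counts with ``risky`` as the positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def TPR(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else 0.0

    @property
    def FPR(self) -> float:
        d = self.FP + self.TN
        return self.FP / d if d else 0.0

    def as_array(self) -> np.ndarray:
        """Rows = true class (risky, neutral), cols = predicted."""
        return np.array([[self.TP, self.FN], [self.FP, self.TN]], dtype=float)


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    t = np.asarray(y_true) == POSITIVE
    p = np.asarray(y_pred) == POSITIVE
    return ConfusionMatrix(
        TP=int(np.sum(t & p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
        TN=int(np.sum(~t & ~p)),
    )


def trapezoid_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by the trapezoidal rule on the score-sorted ROC curve.

    Ties in score collapse into single ROC steps, so the trapezoid
    equals the Mann-Whitney pair-counting estimator with ties counted
    half.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.0
    order = np.argsort(-s, kind="mergesort")
    y, s = y[order], s[order]
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], int)
    cut = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[cut].astype(float)
    fps = np.cumsum(~y)[cut].astype(float)
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.sum(np.diff(fpr) * (tpr[:-1] + tpr[1:]) / 2.0))


def weighted_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray
) -> dict[str, float]:
    """Accuracy plus class-weighted precision/recall/F1/ROC-AUC.

    Class weights are proportional to the true class sizes in the scored
    set.  Degenerate denominators (no predicted positives for a class)
    contribute 0 for that class's term.  ``scores`` are
    higher-means-more-risky decision scores.
    """
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("empty input")
    conf = confusion_from_labels(y_true, y_pred)
    n = conf.TP + conf.FP + conf.FN + conf.TN
    acc = (conf.TP + conf.TN) / n

    # per-class counts, treating each class as positive in turn
    per_class = {
        POSITIVE: (conf.TP, conf.FP, conf.FN),
        NEGATIVE: (conf.TN, conf.FN, conf.FP),
    }
    n_c = {POSITIVE: conf.TP + conf.FN, NEGATIVE: conf.TN + conf.FP}
    w = {c: n_c[c] / n for c in per_class}

    precision = recall = f1 = auc = 0.0
    is_pos = y_true == POSITIVE
    for c, (tp, fp, fn) in per_class.items():
        prec_c = tp / (tp + fp) if tp + fp else 0.0
        rec_c = tp / (tp + fn) if tp + fn else 0.0
        f1_c = (
            2 * prec_c * rec_c / (prec_c + rec_c) if prec_c + rec_c else 0.0
        )
        auc_c = trapezoid_auc(
            is_pos if c == POSITIVE else ~is_pos,
            scores if c == POSITIVE else -np.asarray(scores, dtype=float),
        )
        precision += w[c] * prec_c
        recall += w[c] * rec_c
        f1 += w[c] * f1_c
        auc += w[c] * auc_c
    return {
        "accuracy": acc,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "roc_auc": auc,
    }


def aggregate_confusion(confusions: list[ConfusionMatrix]) -> np.ndarray:
    """Mean of per-iteration row-normalised percentage matrices.

    Rows = true class (risky, neutral); each row of each iteration is
    normalised to percentages before averaging, so every aggregated row
    sums to 100.
    """
    if not confusions:
        raise ValueError("need at least one confusion matrix")
    mats = []
    for c in confusions:
        m = c.as_array()
        sums = m.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        mats.append(100.0 * m / sums)
    return np.mean(mats, axis=0)


def significance_vs_chance(metric_series: np.ndarray, chance: float = 0.5):
    """One-sample, one-tailed t-test of mean(metric) > chance.

    Returns ``(p_value, stars)``; a zero-variance series gets the
    conservative ``p = 1``.
    """
    x = np.asarray(metric_series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0.0:
        return 1.0, ""
    t, p = stats.ttest_1samp(x, chance, alternative="greater")
    return float(p), stars_for(float(p))


def stars_for(p: float) -> str:
    for level, s in STAR_LEVELS:
        if p < level:
            return s
    return ""


# --------------------------------------------------------------- validation


@dataclass
class MetricsReport:
    """Per-iteration and aggregated LPSO results for a set of classifiers."""

    per_iteration: pd.DataFrame  # columns: iteration, seed, classifier, 5 metrics
    mean_metrics: pd.DataFrame  # classifiers x metrics
    confusion_pct: dict[str, np.ndarray]  # classifier -> 2x2 percentage matrix
    p_values: pd.DataFrame  # classifiers x metrics, one-tailed vs 0.5
    stars: pd.DataFrame = field(default=None)

    def significant(self, classifier: str, metric: str = "roc_auc") -> bool:
        return bool(self.stars.loc[classifier, metric] != "")


def _decision_scores(model, X) -> np.ndarray:
    """Higher-means-positive score; predict_proba if available else
    decision_function."""
    if hasattr(model, "predict_proba"):
        classes = list(model.classes_)
        return model.predict_proba(X)[:, classes.index(POSITIVE)]
    scores = model.decision_function(X)
    # sklearn's decision_function is oriented towards classes_[1]
    return scores if model.classes_[1] == POSITIVE else -scores


def run_validation(
    fm: FeatureMatrix,
    plan: SplitPlan,
    classifiers: dict[str, object] | None = None,
) -> MetricsReport:
    """Fit/score every classifier over every LPSO iteration.

    Features are z-scored per fold with train-fold statistics (inside an
    sklearn pipeline).  Model random states are re-derived from each
    iteration's seed so the report is reproducible.
    """
    classifiers = classifiers or default_classifiers()
    X = fm.values
    y = fm.labels
    subjects = fm.subject_ids

    rows = []
    confusions: dict[str, list[ConfusionMatrix]] = {name: [] for name in classifiers}
    for it, (seed, test_subj, train_subj) in enumerate(
        zip(plan.seeds, plan.test_subjects, plan.train_subjects)
    ):
        test_mask = np.isin(subjects, test_subj)
        train_mask = np.isin(subjects, train_subj)
        if np.any(test_mask & train_mask):  # pragma: no cover - plan contract
            raise AssertionError("subject leakage between train and test")
        X_tr, y_tr = X[train_mask], y[train_mask]
        X_te, y_te = X[test_mask], y[test_mask]
        for name, proto in classifiers.items():
            model = clone(proto)
            if "random_state" in model.get_params():
                model.set_params(random_state=seed)
            pipe = make_pipeline(StandardScaler(), model)
            pipe.fit(X_tr, y_tr)
            y_pred = pipe.predict(X_te)
            scores = _decision_scores(pipe[-1], pipe[:-1].transform(X_te))
            m = weighted_metrics(y_te, y_pred, scores)
            confusions[name].append(confusion_from_labels(y_te, y_pred))
            rows.append({"iteration": it, "seed": seed, "classifier": name, **m})

    per_iter = pd.DataFrame(rows)
    mean_metrics = per_iter.groupby("classifier")[list(METRICS)].mean()
    p_values = pd.DataFrame(
        {
            metric: {
                name: significance_vs_chance(
                    per_iter.loc[per_iter["classifier"] == name, metric]
                )[0]
                for name in classifiers
            }
            for metric in METRICS
        }
    )
    stars = p_values.map(stars_for)
    confusion_pct = {
        name: aggregate_confusion(conf) for name, conf in confusions.items()
    }
    return MetricsReport(
        per_iteration=per_iter,
        mean_metrics=mean_metrics,
        confusion_pct=confusion_pct,
        p_values=p_values,
        stars=stars,
    )
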