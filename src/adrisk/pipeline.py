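"""End-to-end experiment orchestration.

Two experiment designs run over the seven task conditions (ML, MH, SL,
SH, the MSIT/STMT unions, Rest):

* **TFAAT** (time-frequency area average test) — classify on the F24
  features that survive t-test + FDR screening for that condition;
* **PBTST** (prefrontal beta time-series test) — classify on the fixed
  9-window prefrontal-beta feature vector, no screening.

By default TFAAT screening runs on the full condition dataset before
the leave-subjects-out loop.  That mirrors a common reporting style in
which the screened feature table is a result in its own right, but it
leaks selection information across folds; ``screen_within_fold=True``
re-screens inside every training fold instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .evaluation import (
    MetricsReport,
    default_classifiers,
    make_lpso_plan,
    run_validation,
)
from .features import (
    BandScheme,
    FeatureMatrix,
    ScreeningResult,
    TTestFDRScreen,
    reduce_to_F216,
    reduce_to_F24,
    screen_features,
    select_pbtst,
)
from .multitaper import MultitaperConfig, spectrogram

ALL_CONDITIONS = ("ML", "MH", "SL", "SH", "MSIT", "STMT", "Rest")


@dataclass
class ExperimentConfig:
    experiment: str = "TFAAT"  # TFAAT | PBTST
    conditions: tuple[str, ...] = ALL_CONDITIONS
    multitaper: MultitaperConfig = field(default_factory=MultitaperConfig)
    band_scheme: BandScheme = field(default_factory=BandScheme)
    screening_alpha: float = 1e-3
    screen_within_fold: bool = False
    n_test_neutral: int = 5
    n_test_risky: int = 4
    n_iterations: int = 100
    seed_start: int = 42
    classifiers: tuple[str, ...] = ("logreg", "rf", "svm", "gb")

    def __post_init__(self) -> None:
        if self.experiment not in ("TFAAT", "PBTST"):
            raise ValueError(f"unknown experiment {self.experiment!r}")


@dataclass
class ConditionResult:
    condition: str
    features: FeatureMatrix
    screening: ScreeningResult | None
    report: MetricsReport | None
    skipped: str | None = None


@dataclass
class ExperimentReport:
    """Per-condition metrics, screening tables and confusion matrices."""

    config: ExperimentConfig
    conditions: dict[str, ConditionResult]

    def ratio_table(self) -> pd.DataFrame:
        from .features import ratio_report

        return ratio_report(
            {
                c: r.screening
                for c, r in self.conditions.items()
                if r.screening is not None
            }
        )

    def radar_table(self) -> pd.DataFrame:
        """condition x classifier rows with the five mean metrics + stars."""
        rows = []
        for cond, res in self.conditions.items():
            if res.report is None:
                continue
            for clf, metrics in res.report.mean_metrics.iterrows():
                rows.append(
                    {
                        "condition": cond,
                        "classifier": clf,
                        **metrics.to_dict(),
                        "stars_roc_auc": res.report.stars.loc[clf, "roc_auc"],
                    }
                )
        return pd.DataFrame(rows)


def condition_features(
    epochs: EpochSet,
    condition: str,
    config: ExperimentConfig,
) -> FeatureMatrix:
    """F216 features for one condition (umbrella conditions take the
    union of their demand levels)."""
    sub = epochs.select_condition(condition)
    if sub.n_trials == 0:
        raise ValueError(f"no trials for condition {condition!r}")
    tfr = spectrogram(sub, config.multitaper)
    return reduce_to_F216(tfr, sub.montage, sub.trials_meta, config.band_scheme)


def _screened_f24(
    f216: FeatureMatrix, alpha: float
) -> tuple[FeatureMatrix, ScreeningResult]:
    f24 = reduce_to_F24(f216)
    screening = screen_features(f24, alpha=alpha)
    if screening.total:
        fm = FeatureMatrix(
            f24.values[:, screening.selected],
            screening.selected_names(),
            "F24-screened",
            f24.trials_meta,
        )
    else:
        fm = None
    return fm, screening


def run_experiment(
    epochs: EpochSet, config: ExperimentConfig
) -> ExperimentReport:
    """Run TFAAT or PBTST over every requested condition."""
    available = set(epochs.trials_meta["condition"].unique())
    for cond in config.conditions:
        base = {"MSIT": {"ML", "MH"}, "STMT": {"SL", "SH"}}.get(cond, {cond})
        if not (base & available or cond in available):
            raise ValueError(f"condition {cond!r} missing from the data")

    classifiers = {
        name: clf
        for name, clf in default_classifiers().items()
        if name in config.classifiers
    }
    results: dict[str, ConditionResult] = {}
    for cond in config.conditions:
        f216 = condition_features(epochs, cond, config)
        screening = None
        if config.experiment == "PBTST":
            fm = select_pbtst(f216)
        else:
            fm, screening = _screened_f24(f216, config.screening_alpha)
            if fm is None and not config.screen_within_fold:
                results[cond] = ConditionResult(
                    cond, f216, screening, None, skipped="no features survived screening"
                )
                continue
        plan = make_lpso_plan(
            fm.trials_meta.groupby("subject_id")["group"].first()
            if fm is not None
            else f216.trials_meta.groupby("subject_id")["group"].first(),
            config.n_test_neutral,
            config.n_test_risky,
            config.n_iterations,
            config.seed_start,
        )
        if config.experiment == "TFAAT" and config.screen_within_fold:
            fm24 = reduce_to_F24(f216)
            report = _run_validation_screened(fm24, plan, classifiers, config)
            fm = fm24
        else:
            report = run_validation(fm, plan, classifiers)
        results[cond] = ConditionResult(cond, fm, screening, report)
    return ExperimentReport(config=config, conditions=results)


def _run_validation_screened(fm24, plan, classifiers, config):
    """Leakage-free TFAAT variant: screening refit inside each train fold."""
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    wrapped = {
        name: make_pipeline(
            TTestFDRScreen(alpha=config.screening_alpha, fallback_k=1),
            StandardScaler(),
            clf,
        )
        for name, clf in classifiers.items()
    }
    return run_validation(fm24, plan, wrapped)


def psd_timeseries(
    f216_by_condition: dict[str, FeatureMatrix],
    feature_prefix: str = "Pre_β",
) -> pd.DataFrame:
    """Group-mean prefrontal-beta PSD per analysis window.

    Rows: (condition, group); columns: window 1..9 mean PSD.  Used for
    the working-memory conditions (SL, SH and their union), where a
    planted or physiological group effect shows as the neutral curve
    lying above the risky curve.
    """
    rows = []
    for cond, fm in f216_by_condition.items():
        names = [f"{feature_prefix}_{w}" for w in range(1, 10)]
        idx = [fm.feature_names.index(n) for n in names]
        for group in ("neutral", "risky"):
            mask = fm.labels == group
            if not mask.any():
                raise ValueError(f"no {group} trials for condition {cond!r}")
            curve = fm.values[np.ix_(mask, idx)].mean(axis=0)
            rows.append(
                {"condition": cond, "group": group,
                 **{f"w{w + 1}": curve[w] for w in range(9)}}
            )
    return pd.DataFrame(rows)
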