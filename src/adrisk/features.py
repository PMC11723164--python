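"""Band/region/time feature reduction and mass-univariate screening.

A per-trial time-frequency representation (channels x freq bins x
windows) is reduced to named band-power features:

* **F216** — mean PSD per (scalp region, frequency band, time window):
  6 x 4 x 9 = 216 features named ``Region_Band_Window`` (``Pre_β_3``);
* **F24**  — F216 averaged over the 9 windows: 6 x 4 features;
* **PBTST** — the fixed prefrontal-beta 9-window subset ``Pre_β_1..9``.

Screening is a per-feature two-sample Welch t-test (neutral vs risky
trials, pooled across subjects) with Benjamini-Hochberg FDR correction;
a feature is selected when its q-value falls below the significance
threshold (default 1e-3).  The region-concentration ratio reports what
share of selected features lies in prefrontal or frontal cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.stats.multitest import multipletests

from .montage import ChannelMontage, REGIONS, REGION_ABBR
from .multitaper import TimeFrequencyRepresentation

#: canonical band scheme, Hz, half-open [low, high); a frequency bin
#: belongs to the band containing its centre frequency.
DEFAULT_BANDS = {
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "Beta": (13.0, 30.0),
}

BAND_GREEK = {"Delta": "δ", "Theta": "θ", "Alpha": "α", "Beta": "β"}


@dataclass(frozen=True)
class BandScheme:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (_, hi), (lo2, _) in zip(edges, edges[1:]):
            if lo2 != hi:
                raise ValueError("bands must be contiguous and non-overlapping")

    def bin_masks(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        masks = {}
        for name, (lo, hi) in self.bands.items():
            mask = (freqs >= lo) & (freqs < hi)
            if not mask.any():
                raise ValueError(f"band {name} [{lo}, {hi}) outside frequency grid")
            masks[name] = mask
        return masks


@dataclass
class FeatureMatrix:
    """Trials x named band-power features with carried-over trial metadata."""

    values: np.ndarray
    feature_names: list[str]
    space_tag: str  # F216 | F24 | PBTST
    trials_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = {"F216": 216, "F24": 24, "PBTST": 9}.get(self.space_tag)
        if expected is not None and self.values.shape[1] != expected:
            raise ValueError(
                f"{self.space_tag} must have {expected} features, "
                f"got {self.values.shape[1]}"
            )
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def labels(self) -> np.ndarray:
        return self.trials_meta["group"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.trials_meta["subject_id"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def save_tsv(self, path) -> None:
        df = pd.concat(
            [self.trials_meta.reset_index(drop=True), self.to_frame()], axis=1
        )
        df.to_csv(path, sep="\t", index=False)


def feature_name(region: str, band: str, window: int | None = None) -> str:
    base = f"{REGION_ABBR[region]}_{BAND_GREEK[band]}"
    return base if window is None else f"{base}_{window}"


def f216_feature_names(bands: BandScheme, n_windows: int = 9) -> list[str]:
    """Region-major, band-middle, window-minor naming order."""
    return [
        feature_name(r, b, w + 1)
        for r in REGIONS
        for b in bands.bands
        for w in range(n_windows)
    ]


def reduce_to_F216(
    tfr: TimeFrequencyRepresentation,
    montage: ChannelMontage,
    trials_meta: pd.DataFrame,
    band_scheme: BandScheme | None = None,
) -> FeatureMatrix:
    """Average PSD over band bins, then over region channels, per window."""
    bands = band_scheme or BandScheme()
    masks = bands.bin_masks(tfr.freqs)
    region_idx = montage.region_indices()
    psd = tfr.psd  # trials x channels x bins x windows
    n_trials, _, _, n_win = psd.shape
    cols = []
    for region in REGIONS:
        ridx = region_idx[region]
        for band in bands.bands:
            # mean over band bins then over region channels -> trials x windows
            cols.append(psd[:, ridx][:, :, masks[band], :].mean(axis=(1, 2)))
    values = np.concatenate(cols, axis=1).reshape(n_trials, -1)
    names = f216_feature_names(bands, n_win)
    return FeatureMatrix(values, names, "F216", trials_meta.reset_index(drop=True))


def reduce_to_F24(f216: FeatureMatrix) -> FeatureMatrix:
    """Average the 9 window indices away: one feature per (region, band)."""
    if f216.space_tag != "F216":
        raise ValueError(f"expected F216 input, got {f216.space_tag}")
    n_win = len(f216.feature_names) // 24
    values = f216.values.reshape(len(f216.values), 24, n_win).mean(axis=2)
    names = [name.rsplit("_", 1)[0] for name in f216.feature_names[::n_win]]
    return FeatureMatrix(values, names, "F24", f216.trials_meta)


def select_pbtst(f216: FeatureMatrix) -> FeatureMatrix:
    """The fixed prefrontal-beta time-series subset ``Pre_β_1..9``."""
    if f216.space_tag != "F216":
        raise ValueError(f"expected F216 input, got {f216.space_tag}")
    wanted = [f"Pre_β_{w}" for w in range(1, 10)]
    try:
        idx = [f216.feature_names.index(n) for n in wanted]
    except ValueError as err:
        raise ValueError(f"missing prefrontal-beta features: {err}") from err
    return FeatureMatrix(f216.values[:, idx], wanted, "PBTST", f216.trials_meta)


@dataclass
class ScreeningResult:
    """Per-feature Welch-t / BH-FDR screening outcome."""

    feature_names: list[str]
    t_stats: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    selected: np.ndarray  # boolean, q < alpha
    alpha: float

    @property
    def total(self) -> int:
        return int(self.selected.sum())

    @property
    def pre_f(self) -> int:
        """Selected features in prefrontal or frontal cortex."""
        sel = np.asarray(self.feature_names)[self.selected]
        return int(sum(n.startswith(("Pre_", "F_")) for n in sel))

    @property
    def ratio(self) -> float:
        return prefrontal_ratio(self.total, self.pre_f)

    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]


def prefrontal_ratio(total: int, pre_f: int) -> float:
    """PreF / Total x 100, rounded to 2 decimals; 0 when nothing selected."""
    if pre_f > total:
        raise ValueError("pre_f cannot exceed total")
    if total == 0:
        return 0.0
    return round(pre_f / total * 100.0, 2)


class TTestFDRScreen(SelectorMixin, BaseEstimator):
    """Mass-univariate two-sample screening as an sklearn feature selector.

    Per feature, a Welch two-sample t-test between the two label groups;
    p-values corrected with the Benjamini-Hochberg step-up procedure;
    features kept when ``q < alpha``.  Constant features (undefined t)
    get ``p = 1``.

    ``fallback_k`` keeps the k smallest-q features when nothing passes
    the threshold (used when the selector runs inside a classification
    pipeline that cannot operate on an empty feature set); the default 0
    keeps the strict empty selection.
    """

    def __init__(self, alpha: float = 1e-3, positive_label: str = "risky",
                 fallback_k: int = 0):
        self.alpha = alpha
        self.positive_label = positive_label
        self.fallback_k = fallback_k

    def fit(self, X, y):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        X = validate_data(self, X, ensure_min_samples=2)
        y = np.asarray(y)
        pos = y == self.positive_label
        if pos.all() or (~pos).all():
            raise ValueError("both groups must be non-empty")
        a, b = X[~pos], X[pos]  # neutral minus risky t-statistic sign
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        degenerate = ~np.isfinite(t)
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
        _, q, _, _ = multipletests(p, alpha=self.alpha, method="fdr_bh")
        self.t_stats_ = t
        self.p_values_ = p
        self.q_values_ = q
        selected = q < self.alpha
        if not selected.any() and self.fallback_k > 0:
            selected = np.zeros_like(selected)
            selected[np.argsort(q, kind="stable")[: self.fallback_k]] = True
        self.selected_ = selected
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.selected_


def screen_features(
    fm: FeatureMatrix, labels: np.ndarray | None = None, alpha: float = 1e-3
) -> ScreeningResult:
    """Screen a feature matrix; labels default to the carried group column."""
    y = fm.labels if labels is None else np.asarray(labels)
    sel = TTestFDRScreen(alpha=alpha).fit(fm.values, y)
    return ScreeningResult(
        feature_names=list(fm.feature_names),
        t_stats=sel.t_stats_,
        p_values=sel.p_values_,
        q_values=sel.q_values_,
        selected=sel.selected_,
        alpha=alpha,
    )


def ratio_report(results: dict[str, ScreeningResult]) -> pd.DataFrame:
    """Per-condition (Total, PreF, Ratio) table of screened features."""
    if not results:
        raise ValueError("empty results map")
    rows = [
        {
            "condition": cond,
            "Total": res.total,
            "PreF": res.pre_f,
            "Ratio": res.ratio,
            "features": ", ".join(res.selected_names()),
        }
        for cond, res in results.items()
    ]
    return pd.DataFrame(rows).set_index("condition")
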