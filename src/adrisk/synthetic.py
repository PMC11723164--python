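"""Synthetic two-group event-related EEG with a planted prefrontal-beta effect.

Emulates the structure of a genetic-risk EEG study: two subject groups
("neutral" carriers of no risk allele, "risky" single-allele carriers),
several task conditions with imbalanced per-subject trial counts, and a
group-level reduction of prefrontal beta-band power in the risky group.

Signal model (per trial, per channel):

* AR(1)-filtered Gaussian broadband noise (1/f-like spectral decay),
  independent per channel;
* one band-limited Gaussian "oscillation" per canonical band (delta,
  theta, alpha, beta), shared by all channels of a scalp region within a
  trial — this is what gives band x region structure to the features;
* in prefrontal channels only, an extra beta-band component whose
  amplitude envelope follows a 9-window temporal profile (activation at
  stimulus onset, minimum near 0.6 s, late rebound) and whose amplitude
  is scaled by ``1 - beta_effect`` for risky subjects.

Between-subject variability enters as a log-normal gain on the
prefrontal beta source; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet, concat_epochs, make_trials_meta
from .montage import ChannelMontage, REGIONS, default_montage

#: canonical EEG bands, Hz, half-open [low, high)
BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: per-condition trial-count scale of a mid-sized task-EEG study:
#: interference task ~77/73 trials (low/high demand), working-memory task
#: ~64/53, resting segments more plentiful.
TRIAL_COUNT_MEANS = {"ML": 77, "MH": 73, "SL": 64, "SH": 53, "Rest": 100}
TRIAL_COUNT_SDS = {"ML": 7, "MH": 8, "SL": 6, "SH": 9, "Rest": 10}

#: beta-envelope gain per analysis window (9 windows over -80..1200 ms):
#: strong activation at onset, minimum in the window centred near 0.6 s,
#: partial late rebound.
DEFAULT_TEMPORAL_PROFILE = (1.0, 1.0, 0.75, 0.5, 0.35, 0.45, 0.6, 0.7, 0.75)


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults mirror the study conditions."""

    n_neutral_subjects: int = 21
    n_risky_subjects: int = 18
    trials_per_subject_mean: dict[str, int] | int = field(
        default_factory=lambda: dict(TRIAL_COUNT_MEANS)
    )
    trials_per_subject_sd: dict[str, int] | int = field(
        default_factory=lambda: dict(TRIAL_COUNT_SDS)
    )
    conditions: tuple[str, ...] = ("ML", "MH", "SL", "SH", "Rest")
    fs: float = 250.0
    epoch_window: tuple[float, float] = (-80.0, 1200.0)  # ms, half-open
    n_channels: int = 60
    montage: ChannelMontage | None = None
    beta_effect: float = 0.0
    temporal_profile: tuple[float, ...] = DEFAULT_TEMPORAL_PROFILE
    subject_sd: float = 0.2
    noise_sd: float = 5.0
    osc_amplitude: float = 3.0
    beta_amplitude: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neutral_subjects <= 0 or self.n_risky_subjects <= 0:
            raise ValueError("subject counts must be positive")
        if not 0.0 <= self.beta_effect < 1.0:
            raise ValueError("beta_effect must be in [0, 1)")
        if self.montage is None:
            self.montage = default_montage(self.n_channels)
        elif self.montage.n_channels != self.n_channels:
            raise ValueError("montage size does not match n_channels")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.fs / 1000.0))

    def mean_for(self, condition: str) -> float:
        m = self.trials_per_subject_mean
        return float(m[condition]) if isinstance(m, dict) else float(m)

    def sd_for(self, condition: str) -> float:
        s = self.trials_per_subject_sd
        return float(s[condition]) if isinstance(s, dict) else float(s)


def _ar1_noise(rng: np.random.Generator, shape: tuple, a: float = 0.95) -> np.ndarray:
    """AR(1) process along the last axis; approximates 1/f spectral decay."""
    white = rng.standard_normal(shape)
    # lfilter implements x[t] = a x[t-1] + w[t]
    return signal.lfilter([1.0], [1.0, -a], white, axis=-1) * np.sqrt(1 - a * a)


def _band_sos(low: float, high: float, fs: float):
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _beta_envelope(
    profile: tuple[float, ...], n_samples: int, fs: float, t0_ms: float,
    nperseg: int = 64, step: int = 32,
) -> np.ndarray:
    """Interpolate the per-window gain profile onto the sample grid."""
    n_windows = len(profile)
    centers = (np.arange(n_windows) * step + nperseg / 2.0) / fs + t0_ms / 1000.0
    t = t0_ms / 1000.0 + np.arange(n_samples) / fs
    return np.interp(t, centers, np.asarray(profile, dtype=float))


def generate_dataset(config: SyntheticConfig) -> EpochSet:
    """Generate a two-group epoched dataset per ``config``.

    Deterministic given ``config.seed``; subject identities ``N01..``
    (neutral) and ``R01..`` (risky).
    """
    fs = config.fs
    n_samp = config.n_samples
    montage = config.montage
    assert montage is not None
    region_idx = montage.region_indices()
    pre_idx = np.asarray(region_idx["prefrontal"])

    band_filters = {b: _band_sos(lo, hi, fs) for b, (lo, hi) in BANDS.items()}
    beta_filter = band_filters["beta"]
    envelope = _beta_envelope(
        config.temporal_profile, n_samp, fs, config.epoch_window[0]
    )

    root = np.random.SeedSequence(config.seed)
    subjects = [(f"N{i + 1:02d}", "neutral") for i in range(config.n_neutral_subjects)]
    subjects += [(f"R{i + 1:02d}", "risky") for i in range(config.n_risky_subjects)]
    subject_seeds = root.spawn(len(subjects))

    parts: list[EpochSet] = []
    for (subj, group), sseq in zip(subjects, subject_seeds):
        rng = np.random.default_rng(sseq)
        # subject_sd is a log-POWER sd; amplitude gain is exp(half the draw)
        subj_gain = float(np.exp(0.5 * rng.normal(0.0, config.subject_sd)))
        beta_scale = subj_gain * (
            (1.0 - config.beta_effect) if group == "risky" else 1.0
        )
        for cond in config.conditions:
            n_trials = max(
                10,
                int(round(rng.normal(config.mean_for(cond), config.sd_for(cond)))),
            )
            data = config.noise_sd * _ar1_noise(
                rng, (n_trials, montage.n_channels, n_samp)
            )
            # region-shared narrowband oscillations
            for band, sos in band_filters.items():
                src = signal.sosfilt(
                    sos, rng.standard_normal((n_trials, len(REGIONS), n_samp)), axis=-1
                )
                for r, region in enumerate(REGIONS):
                    idx = region_idx[region]
                    data[:, idx, :] += config.osc_amplitude * src[:, r, None, :]
            # planted prefrontal beta component with temporal envelope
            beta_src = signal.sosfilt(
                beta_filter, rng.standard_normal((n_trials, n_samp)), axis=-1
            )
            data[:, pre_idx, :] += (
                config.beta_amplitude * beta_scale * (beta_src * envelope)[:, None, :]
            )
            rt = rng.uniform(400.0, 1100.0, n_trials)
            meta = make_trials_meta(
                subject_id=subj,
                group=group,
                condition=cond,
                response_time=np.nan if cond == "Rest" else rt,
                correct=np.nan if cond == "Rest" else True,
            )
            parts.append(
                EpochSet(
                    data=data.astype(np.float32),
                    fs=fs,
                    t0_offset=config.epoch_window[0],
                    montage=montage,
                    trials_meta=meta,
                )
            )
    return concat_epochs(parts)
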