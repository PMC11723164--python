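"""Epoch-level conditioning and trial selection.

Re-referencing to the averaged mastoids, zero-phase 1-30 Hz bandpass,
behavioural/amplitude trial filters and resting-state segmentation.
The bandpass follows the ERP convention of stating *half-amplitude*
(-6 dB) cut-offs with a 12 dB/octave roll-off: a second-order
Butterworth per edge applied forward-backward, with the design cut-off
pre-warped so the half-amplitude point of the two-pass response lands on
the requested frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet, make_trials_meta
from .montage import ChannelMontage


@dataclass(frozen=True)
class TrialFilterSpec:
    """Behavioural and amplitude gates for task trials.

    Response times are in ms; the upper bound is task-specific (1500 ms
    for the interference task, 2000 ms for the memory task).  Any single
    channel whose peak-to-peak amplitude exceeds ``p2p_threshold``
    (microvolts) rejects the whole trial.
    """

    min_rt: float = 200.0
    max_rt: float = 1500.0
    require_correct: bool = True
    p2p_threshold: float = 150.0

    def __post_init__(self) -> None:
        if not self.min_rt < self.max_rt:
            raise ValueError("min_rt must be < max_rt")
        if self.p2p_threshold <= 0:
            raise ValueError("p2p_threshold must be positive")


def rereference_mastoid(
    epochs: EpochSet, left_label: str = "TP9", right_label: str = "TP10"
) -> EpochSet:
    """Subtract the average of the two mastoid channels from every channel.

    Reference channels are retained in the output.
    """
    names = epochs.channel_names
    for lab in (left_label, right_label):
        if lab not in names:
            raise ValueError(f"reference channel {lab!r} not in montage")
    li, ri = names.index(left_label), names.index(right_label)
    ref = 0.5 * (epochs.data[:, li, :] + epochs.data[:, ri, :])
    return replace(epochs, data=epochs.data - ref[:, None, :])


def _halfamp_butter2_sos(edge: float, btype: str, fs: float):
    """2nd-order Butterworth whose *two-pass* response is -6 dB at `edge`.

    A forward-backward 2nd-order Butterworth attenuates by |H|^2; its
    half-amplitude point sits where the single-pass response is -3 dB,
    i.e. exactly at the Butterworth natural frequency.  So no warp factor
    is needed beyond designing at the requested edge.
    """
    return signal.butter(2, edge, btype=btype, fs=fs, output="sos")


def bandpass(epochs: EpochSet, low: float = 1.0, high: float = 30.0) -> EpochSet:
    """Zero-phase band-limitation with half-amplitude cut-offs at (low, high).

    Implemented as cascaded high-pass and low-pass second-order
    Butterworth sections applied with ``sosfiltfilt`` (12 dB/octave per
    edge, zero phase).
    """
    if not 0 < low < high < epochs.fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) at fs={epochs.fs}")
    hp = _halfamp_butter2_sos(low, "highpass", epochs.fs)
    lp = _halfamp_butter2_sos(high, "lowpass", epochs.fs)
    out = signal.sosfiltfilt(hp, epochs.data, axis=-1)
    out = signal.sosfiltfilt(lp, out, axis=-1)
    return replace(epochs, data=out)


def filter_trials(epochs: EpochSet, spec: TrialFilterSpec) -> EpochSet:
    """Keep trials passing correctness, response-time and amplitude gates.

    Gates (all inclusive): ``correct`` is true when required;
    ``min_rt <= RT <= max_rt``; per-channel peak-to-peak amplitude
    ``<= p2p_threshold``.  Trial order is preserved; an empty result is
    allowed.
    """
    meta = epochs.trials_meta
    rt = pd.to_numeric(meta["response_time"], errors="coerce").to_numpy(dtype=float)
    keep = (rt >= spec.min_rt) & (rt <= spec.max_rt)
    if spec.require_correct:
        correct = meta["correct"].fillna(False).astype(bool).to_numpy()
        keep &= correct
    p2p = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)  # trials x channels
    keep &= (p2p <= spec.p2p_threshold).all(axis=1)
    return epochs.select_trials(keep)


def segment_resting(
    continuous: np.ndarray,
    fs: float,
    montage: ChannelMontage,
    interval: float = 1.2,
    subject_id: str = "unknown",
    group: str = "neutral",
) -> EpochSet:
    """Cut a continuous channels x samples recording into fixed epochs.

    Non-overlapping consecutive windows of exactly ``interval`` seconds
    (virtual stimulus zero at each window start); the trailing remainder
    is discarded.  Condition is ``Rest``.
    """
    continuous = np.atleast_2d(np.asarray(continuous))
    n_per = int(round(interval * fs))
    if not np.isclose(n_per, interval * fs):
        raise ValueError("interval x fs must be an integer sample count")
    n_epochs = continuous.shape[1] // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {continuous.shape[1] / fs:.3f}s shorter than one "
            f"{interval}s interval"
        )
    segs = continuous[:, : n_epochs * n_per].reshape(
        continuous.shape[0], n_epochs, n_per
    )
    data = np.moveaxis(segs, 1, 0)  # epochs x channels x samples
    meta = make_trials_meta(
        subject_id=[subject_id] * n_epochs,
        group=group,
        condition="Rest",
    )
    return EpochSet(
        data=data, fs=fs, t0_offset=0.0, montage=montage, trials_meta=meta
    )


def decimate_epochs(epochs: EpochSet, factor: int) -> EpochSet:
    """Anti-aliased integer-factor downsampling (plumbing for 1000->250 Hz)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return epochs
    out = signal.decimate(epochs.data, factor, axis=-1, zero_phase=True)
    return replace(epochs, data=out, fs=epochs.fs / factor)
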