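"""Optional readers for standard EEG file formats.

Thin adapters from MNE continuous recordings (EDF/EDF+, BrainVision
``.vhdr``) to this package's containers.  MNE stores signals in volts;
epochs here are in microvolts, so the adapter rescales.  Imported
lazily: the rest of the package works without ``mne`` installed.
"""

from __future__ import annotations

import numpy as np

from .epochs import EpochSet
from .montage import ChannelMontage, default_montage
from .preprocess import segment_resting


def from_mne_raw(raw, montage: ChannelMontage | None = None):
    """Extract (data_uV, fs, channel_names) from an ``mne.io.Raw``.

    Channels are reordered to the montage's order when one is given;
    channels absent from the montage are dropped.
    """
    names = list(raw.ch_names)
    data = raw.get_data() * 1e6  # volts -> microvolts
    if montage is not None:
        idx = []
        for ch in montage.channel_names:
            if ch not in names:
                raise ValueError(f"channel {ch!r} missing from the recording")
            idx.append(names.index(ch))
        data = data[idx]
        names = list(montage.channel_names)
    return data, float(raw.info["sfreq"]), names


def read_continuous(path, montage: ChannelMontage | None = None):
    """Read an EDF/EDF+ or BrainVision recording via MNE.

    Returns ``(data_uV, fs, channel_names)`` for downstream segmentation.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    return from_mne_raw(raw, montage)


def segment_raw_resting(
    raw_or_path,
    montage: ChannelMontage | None = None,
    interval: float = 1.2,
    subject_id: str = "unknown",
    group: str = "neutral",
) -> EpochSet:
    """Resting-state pseudo-epochs straight from a file or Raw object."""
    if isinstance(raw_or_path, (str, bytes)) or hasattr(raw_or_path, "__fspath__"):
        data, fs, names = read_continuous(raw_or_path, montage)
    else:
        data, fs, names = from_mne_raw(raw_or_path, montage)
    if montage is None:
        candidate = default_montage(len(names)) if len(names) % 6 == 0 else None
        if candidate is None or set(candidate.channel_names) != set(names):
            raise ValueError("provide a montage for non-standard channel sets")
        montage = candidate
    return segment_resting(
        data, fs, montage, interval, subject_id=subject_id, group=group
    )
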