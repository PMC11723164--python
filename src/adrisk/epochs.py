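"""The epoched-EEG exchange container and its on-disk format.

``EpochSet`` is the universal container passed between every stage:
a trials x channels x samples microvolt array, per-trial metadata
(subject, group, task condition, response time, correctness) and the
channel montage.  On disk it is a raw little-endian float32 array plus a
JSON sidecar holding sampling rate, epoch timing, channel names, the
region map and the trial table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import ChannelMontage

CONDITIONS = ("ML", "MH", "SL", "SH", "MSIT", "STMT", "Rest")
GROUPS = ("neutral", "risky")

#: composite task conditions are unions of their demand-level subclasses
CONDITION_UNIONS = {"MSIT": ("ML", "MH"), "STMT": ("SL", "SH")}

META_COLUMNS = ("subject_id", "group", "condition", "response_time", "correct")


@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-trial metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    t0_offset : float
        Epoch start relative to stimulus onset, in ms (negative = pre-stimulus).
    montage : ChannelMontage
    trials_meta : DataFrame
        One row per trial with columns ``subject_id``, ``group``,
        ``condition``, ``response_time`` (ms, NaN when absent) and
        ``correct`` (boolean, NaN when absent).
    """

    data: np.ndarray
    fs: float
    t0_offset: float
    montage: ChannelMontage
    trials_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[1]} channels, montage has "
                f"{self.montage.n_channels}"
            )
        if len(self.trials_meta) != self.data.shape[0]:
            raise ValueError("trials_meta length must equal trial count")
        # one group label per subject
        groups = self.trials_meta.groupby("subject_id")["group"].nunique()
        if (groups > 1).any():
            bad = groups[groups > 1].index.tolist()
            raise ValueError(f"subjects with conflicting group labels: {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.montage.channel_names

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset (half-open epoch)."""
        return self.t0_offset + np.arange(self.n_samples) * 1000.0 / self.fs

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            trials_meta=self.trials_meta.iloc[np.flatnonzero(mask)]
            if mask.dtype == bool
            else self.trials_meta.iloc[mask],
        )

    def select_condition(self, condition: str) -> "EpochSet":
        """Trials of one condition; MSIT/STMT select the union of their
        demand-level subclasses."""
        cond = self.trials_meta["condition"].to_numpy()
        wanted = CONDITION_UNIONS.get(condition, (condition,)) + (condition,)
        return self.select_trials(np.isin(cond, wanted))

    def subject_groups(self) -> pd.Series:
        """group label per subject_id."""
        return self.trials_meta.groupby("subject_id")["group"].first()

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        """Write ``<path>.dat`` (little-endian float32) + ``<path>.json``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arr = np.ascontiguousarray(self.data, dtype="<f4")
        arr.tofile(path.with_suffix(".dat"))
        meta = {
            "shape": list(self.data.shape),
            "dtype": "<f4",
            "fs": self.fs,
            "t0_offset": self.t0_offset,
            "channel_names": list(self.montage.channel_names),
            "region_of": dict(self.montage.region_of),
            "trials_meta": json.loads(
                self.trials_meta.reset_index(drop=True).to_json(orient="split")
            ),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        shape = tuple(meta["shape"])
        data = np.fromfile(path.with_suffix(".dat"), dtype=meta["dtype"]).reshape(shape)
        montage = ChannelMontage(tuple(meta["channel_names"]), meta["region_of"])
        from io import StringIO

        tm = pd.read_json(
            StringIO(json.dumps(meta["trials_meta"])),
            orient="split",
            convert_dates=False,
        )
        return cls(
            data=data,
            fs=float(meta["fs"]),
            t0_offset=float(meta["t0_offset"]),
            montage=montage,
            trials_meta=tm,
        )


def make_trials_meta(
    subject_id,
    group,
    condition,
    response_time=None,
    correct=None,
) -> pd.DataFrame:
    """Assemble a trial-metadata table; scalars broadcast."""
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "condition": condition,
            "response_time": np.nan if response_time is None else response_time,
            "correct": np.nan if correct is None else correct,
        }
    )
    return df


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Stack EpochSets sharing fs, epoch timing and montage."""
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if (
            p.fs != first.fs
            or p.t0_offset != first.t0_offset
            or p.channel_names != first.channel_names
            or p.n_samples != first.n_samples
        ):
            raise ValueError("EpochSets are not compatible for concatenation")
    return EpochSet(
        data=np.concatenate([p.data for p in parts], axis=0),
        fs=first.fs,
        t0_offset=first.t0_offset,
        montage=first.montage,
        trials_meta=pd.concat(
            [p.trials_meta for p in parts], ignore_index=True
        ),
    )
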