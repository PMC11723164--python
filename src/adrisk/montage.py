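"""Channel montages and the six-region scalp partition.

Sixty 10-10 electrode labels are partitioned into six scalp regions:
prefrontal, frontal, temporal, central, parietal and occipital.  Region
membership drives the spatial averaging step of the band-power feature
reduction, so every channel must belong to exactly one region and every
region must be non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS = ("prefrontal", "frontal", "temporal", "central", "parietal", "occipital")

REGION_ABBR = {
    "prefrontal": "Pre",
    "frontal": "F",
    "temporal": "T",
    "central": "C",
    "parietal": "Par",
    "occipital": "O",
}

# 60-channel 10-10 montage; FCz is excluded (online reference position).
_MONTAGE_60 = {
    "prefrontal": ["Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8"],
    "frontal": ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"],
    "temporal": ["FT7", "FT8", "T7", "T8", "TP7", "TP8", "TP9", "TP10"],
    "central": ["FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "C3", "C1", "Cz", "C2", "C4"],
    "parietal": [
        "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
        "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    ],
    "occipital": ["PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2"],
}

_MONTAGE_12 = {
    "prefrontal": ["Fp1", "Fp2"],
    "frontal": ["F3", "F4"],
    "temporal": ["T7", "T8"],
    "central": ["C3", "C4"],
    "parietal": ["P3", "P4"],
    "occipital": ["O1", "O2"],
}


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered channel labels plus a channel -> region map."""

    channel_names: tuple[str, ...]
    region_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        missing = [ch for ch in self.channel_names if ch not in self.region_of]
        if missing:
            raise ValueError(f"channels without a region: {missing}")
        bad = {r for r in self.region_of.values() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")
        present = {self.region_of[ch] for ch in self.channel_names}
        empty = [r for r in REGIONS if r not in present]
        if empty:
            raise ValueError(f"empty regions: {empty}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def region_indices(self) -> dict[str, list[int]]:
        """Channel indices per region, in montage order."""
        out: dict[str, list[int]] = {r: [] for r in REGIONS}
        for i, ch in enumerate(self.channel_names):
            out[self.region_of[ch]].append(i)
        return out


def default_montage(n_channels: int = 60) -> ChannelMontage:
    """Deterministic six-region montage.

    ``n_channels=60`` returns the canonical 10-10 layout; ``n_channels=12``
    a symmetric two-per-region fixture; any other multiple of six gets
    generic region-numbered labels.
    """
    if n_channels == 60:
        table = _MONTAGE_60
    elif n_channels == 12:
        table = _MONTAGE_12
    elif n_channels > 0 and n_channels % 6 == 0:
        per = n_channels // 6
        table = {
            r: [f"{REGION_ABBR[r]}{i + 1}" for i in range(per)] for r in REGIONS
        }
    else:
        raise ValueError(
            f"n_channels must be a positive multiple of 6, got {n_channels}"
        )
    names: list[str] = []
    region_of: dict[str, str] = {}
    for region in REGIONS:
        for ch in table[region]:
            names.append(ch)
            region_of[ch] = region
    return ChannelMontage(tuple(names), region_of)
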