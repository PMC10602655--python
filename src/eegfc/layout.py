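"""Electrode layouts.

The default layout is the 19-channel international 10-20 montage used in
routine clinical EEG, with each electrode tagged by scalp region.  Region
tags drive the group-specific coupling templates of the synthetic
generator (e.g. fronto-temporal pairs for the FTD-like group).
"""

from __future__ import annotations

from dataclasses import dataclass, field


# 10-20 electrode -> scalp region
_DEFAULT_REGIONS = {
    "Fp1": "frontal", "Fp2": "frontal", "F7": "frontal", "F3": "frontal",
    "Fz": "frontal", "F4": "frontal", "F8": "frontal",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "C3": "central", "Cz": "central", "C4": "central",
    "P3": "parietal", "Pz": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
}

#: Channel ordering of the default montage.
DEFAULT_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel labels plus a label -> region map."""

    labels: tuple[str, ...] = DEFAULT_LABELS
    region_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_REGIONS))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        missing = [l for l in self.labels if l not in self.region_map]
        if missing:
            raise ValueError(f"labels without a region tag: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def channels_in_region(self, region: str) -> list[int]:
        """Indices of all channels tagged with ``region``."""
        return [i for i, l in enumerate(self.labels) if self.region_map[l] == region]


def default_layout() -> ChannelLayout:
    return ChannelLayout()


def generic_layout(n_channels: int, region: str = "central") -> ChannelLayout:
    """A minimal n-channel layout (Ch1..Chn, single region) for toy data."""
    labels = tuple(f"Ch{i + 1}" for i in range(n_channels))
    return ChannelLayout(labels=labels, region_map={l: region for l in labels})
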