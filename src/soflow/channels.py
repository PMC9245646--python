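"""Channel montage, analysis sets, and the anterior-posterior region scheme.

The analysis operates on a 22-channel 10-20 montage. Twelve channels enter
the connectivity stage, grouped into four regions along the
anterior-posterior axis: frontal (F), central (C), parietal (P) and
occipital (O). One midline channel per region (Fz, Cz, Pz, POz) acts as a
source of causal information flow; all twelve act as sinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Full 22-channel recording montage (10-20 names).
MONTAGE_22: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CP2", "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "O2",
)

#: Twelve channels used for connectivity estimation, in fixed order.
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "POz", "O2",
)

#: The four source channels, anterior to posterior.
SOURCE_CHANNELS: tuple[str, ...] = ("Fz", "Cz", "Pz", "POz")

#: Region membership of the analysis channels.
REGIONS: dict[str, tuple[str, ...]] = {
    "F": ("Fz", "F3", "F4"),
    "C": ("Cz", "C3", "C4"),
    "P": ("Pz", "P3", "P4"),
    "O": ("POz", "O1", "O2"),
}

#: Anterior-posterior integer coding shared by channels and regions (1..4).
REGION_INDEX: dict[str, int] = {"F": 1, "C": 2, "P": 3, "O": 4}
SOURCE_INDEX: dict[str, int] = {"Fz": 1, "Cz": 2, "Pz": 3, "POz": 4}


def region_of(channel: str) -> str:
    """Region label of an analysis channel (case-insensitive)."""
    ch = normalize_label(channel)
    for region, members in REGIONS.items():
        if ch in members:
            return region
    raise KeyError(f"channel {channel!r} is not one of the 12 analysis channels")


_CANONICAL = {name.lower(): name for name in MONTAGE_22}


def normalize_label(label: str) -> str:
    """Map a label to its canonical 10-20 spelling; unknown labels pass through."""
    return _CANONICAL.get(label.strip().lower(), label.strip())


@dataclass(frozen=True)
class RegionScheme:
    """Anterior-posterior coding used by the distance predictors.

    Regions are ordered F=1, C=2, P=3, O=4; the midline source channels
    Fz, Cz, Pz, POz carry the index of their own region.
    """

    regions: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(REGIONS))
    region_index: dict[str, int] = field(default_factory=lambda: dict(REGION_INDEX))
    source_index: dict[str, int] = field(default_factory=lambda: dict(SOURCE_INDEX))

    def __post_init__(self) -> None:
        for src, idx in self.source_index.items():
            region = region_of(src)
            if self.region_index[region] != idx:
                raise ValueError(f"source {src} not indexed with its own region")

    def region_of(self, channel: str) -> str:
        return region_of(channel)

    def channel_indices(self, region: str) -> list[int]:
        """Indices (into ANALYSIS_CHANNELS) of a region's members."""
        return [ANALYSIS_CHANNELS.index(ch) for ch in self.regions[region]]


DEFAULT_SCHEME = RegionScheme()
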