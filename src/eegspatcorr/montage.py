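"""Electrode montage: 60 analysis channels on a unit sphere and the 8 scalp regions.

The analysis montage is the 64-channel Neuroscan Quik-Cap layout minus the four
channels outside the standard 10-10 scheme (CB1, CB2, M1, M2).  Channels are
grouped into eight scalp regions (left/right frontal, temporal, parietal and
occipito-temporal) whose cross-region channel pairs form the unit of the
region-pair disruption screen.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANALYSIS_CHANNELS",
    "DEFAULT_REGIONS",
    "Montage",
    "standard_montage",
    "region_channel_pairs",
    "all_channel_pairs",
]

#: The 60 channels retained for analysis (10-10 names, uppercase).
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
)

# Eight scalp regions.  Note: the published left-frontal list repeats F8 (which
# belongs to the right-frontal list); here the left-frontal region uses F3
# instead, restoring left/right symmetry (9 channels each) and disjointness.
# Pass an explicit ``regions`` mapping to standard_montage() to override.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "left_frontal": ("FP1", "AF3", "F7", "F5", "F3", "F1", "FC5", "FC3", "FC1"),
    "right_frontal": ("FP2", "AF4", "F2", "F4", "F6", "F8", "FC2", "FC4", "FC6"),
    "left_temporal": ("FT7", "T7", "TP7"),
    "right_temporal": ("FT8", "T8", "TP8"),
    "left_parietal": ("CP5", "CP3", "CP1", "P7", "P5", "P3", "P1"),
    "right_parietal": ("CP2", "CP4", "CP6", "P2", "P4", "P6", "P8"),
    "left_occipital": ("PO7", "PO5", "PO3", "O1"),
    "right_occipital": ("PO4", "PO6", "PO8", "O2"),
}


@dataclass
class Montage:
    """Channel positions on the unit sphere plus the scalp-region channel lists."""

    positions: dict[str, np.ndarray]
    regions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self) -> None:
        for label, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (3,):
                raise ValueError(f"position of {label} must be a 3-vector")
            norm = np.linalg.norm(pos)
            if not np.isclose(norm, 1.0, atol=1e-6):
                raise ValueError(f"position of {label} is not on the unit sphere")
            self.positions[label] = pos
        for region, chans in self.regions.items():
            missing = [c for c in chans if c not in self.positions]
            if missing:
                raise ValueError(f"region {region} lists unknown channels {missing}")

    @property
    def channels(self) -> list[str]:
        return list(self.positions)

    def position_array(self, labels: list[str] | None = None) -> np.ndarray:
        labels = labels if labels is not None else self.channels
        return np.stack([self.positions[lab] for lab in labels])

    def region_pairs(self) -> list[tuple[str, str]]:
        """All unordered region pairs (28 for the default 8 regions)."""
        return list(itertools.combinations(self.regions, 2))


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit: returns (center, radius)."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def standard_montage(
    channels: tuple[str, ...] | list[str] = ANALYSIS_CHANNELS,
    regions: dict[str, tuple[str, ...]] | None = None,
) -> Montage:
    """Build the analysis montage from the standard 10-05 electrode layout.

    Electrode positions are taken from mne's ``standard_1005`` template,
    sphere-fitted and projected onto the unit sphere (nose along +y, vertex
    along +z).  Only the overall angular configuration matters downstream
    (the spherical-spline Laplacian); absolute head size does not.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        template = mne.channels.make_standard_montage("standard_1005")
    lookup = {name.lower(): name for name in template.ch_names}
    ch_pos = template.get_positions()["ch_pos"]

    missing = [c for c in channels if c.lower() not in lookup]
    if missing:
        raise ValueError(f"channels absent from the 10-05 template: {missing}")

    raw = np.stack([ch_pos[lookup[c.lower()]] for c in channels])
    center, _ = _fit_sphere(raw)
    centered = raw - center
    unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)

    positions = {c: unit[i] for i, c in enumerate(channels)}
    return Montage(positions=positions, regions=dict(regions or DEFAULT_REGIONS))


def region_channel_pairs(
    montage: Montage, region_a: str, region_b: str
) -> list[tuple[str, str]]:
    """All cross-region channel pairs between two distinct regions.

    Pairs are unordered and deduplicated; for disjoint regions the count is
    ``|A| * |B|`` (e.g. 27 for left frontal vs left temporal).
    """
    if region_a == region_b:
        raise ValueError("region_a and region_b must differ")
    for name in (region_a, region_b):
        if name not in montage.regions:
            raise KeyError(f"unknown region {name!r}; known: {list(montage.regions)}")
    seen: set[frozenset[str]] = set()
    pairs: list[tuple[str, str]] = []
    for ca in montage.regions[region_a]:
        for cb in montage.regions[region_b]:
            if ca == cb:
                continue
            key = frozenset((ca, cb))
            if key not in seen:
                seen.add(key)
                pairs.append((ca, cb))
    return pairs


def all_channel_pairs(montage: Montage) -> list[tuple[str, str]]:
    """Every unordered channel pair in the montage (1770 for 60 channels)."""
    return list(itertools.combinations(montage.channels, 2))
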