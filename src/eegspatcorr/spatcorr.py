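"""The instantaneous spatial-correlation statistic psi and its per-condition
median M_psi.

For two envelope-fluctuation phases theta1(t), theta2(t), the wrapped
absolute phase difference Delta(t) = |theta1 - theta2| (wrapped into
[0, pi]) maps linearly onto the unit interval::

    psi(t) = 1 - Delta(t) / pi

so identical phases give psi = 1 (perfect spatial correlation) and
antiphase gives psi = 0.  M_psi is the median of psi(t) over all valid
samples falling inside one task condition's intervals; it is the per-pair,
per-participant summary used by the group screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envelope import PhaseSeries
from .io import ConditionInterval

__all__ = ["PsiSeries", "PairCorrelation", "psi", "m_psi", "pairwise_mpsi"]

#: fixed column order of the pair-correlation table
PAIR_TABLE_COLUMNS = [
    "participant",
    "channel_a",
    "channel_b",
    "carrier_band",
    "envelope_band",
    "condition",
    "m_psi",
    "n_samples",
]


@dataclass
class PsiSeries:
    """psi(t) in [0, 1] for one channel pair."""

    values: np.ndarray
    fs: float
    pair: tuple[str, str]
    carrier_band: str = ""
    envelope_band: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        ok = self.values[self.valid]
        if ok.size and (ok.min() < -1e-12 or ok.max() > 1 + 1e-12):
            raise ValueError("psi values must lie in [0, 1]")


@dataclass(frozen=True)
class PairCorrelation:
    """M_psi for one (participant, channel pair, band, envelope band, condition)."""

    participant: str
    pair: tuple[str, str]
    carrier_band: str
    envelope_band: str
    condition: str
    m_psi: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0 <= self.m_psi <= 1:
            raise ValueError("m_psi must lie in [0, 1]")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


def wrapped_phase_difference(theta1: np.ndarray, theta2: np.ndarray) -> np.ndarray:
    """|theta1 - theta2| wrapped circularly into [0, pi]."""
    d = np.abs(theta1 - theta2) % (2 * np.pi)
    return np.where(d > np.pi, 2 * np.pi - d, d)


def psi(theta1: PhaseSeries, theta2: PhaseSeries) -> PsiSeries:
    """Instantaneous spatial correlation of two envelope-phase series.

    Symmetric in its arguments and invariant under a common phase shift;
    the valid mask is the AND of the input masks.
    """
    if len(theta1.values) != len(theta2.values):
        raise ValueError("phase series have different lengths")
    if theta1.fs != theta2.fs:
        raise ValueError("phase series have different sampling rates")
    if theta1.envelope_band != theta2.envelope_band:
        raise ValueError("phase series are from different envelope bands")
    if theta1.carrier_band != theta2.carrier_band:
        raise ValueError("phase series are from different carrier bands")
    delta = wrapped_phase_difference(theta1.values, theta2.values)
    return PsiSeries(
        1.0 - delta / np.pi,
        theta1.fs,
        pair=(theta1.channel, theta2.channel),
        carrier_band=theta1.carrier_band,
        envelope_band=theta1.envelope_band,
        valid=theta1.valid & theta2.valid,
    )


def condition_sample_mask(
    n: int, fs: float, intervals: list[ConditionInterval], condition: str
) -> np.ndarray:
    """Boolean mask of the samples belonging to a condition's intervals."""
    t = np.arange(n) / fs
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        if iv.condition == condition:
            mask |= (t >= iv.start - 1e-9) & (t < iv.end - 1e-9)
    return mask


def m_psi(
    series: PsiSeries, intervals: list[ConditionInterval], condition: str
) -> PairCorrelation:
    """Median of psi(t) over the valid samples of one condition.

    The median of an even number of samples is the midpoint of the two
    central order statistics (numpy convention).
    """
    mask = condition_sample_mask(len(series.values), series.fs, intervals, condition)
    mask &= series.valid
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError(
            f"no valid psi samples for pair {series.pair} in condition "
            f"{condition!r}"
        )
    return PairCorrelation(
        participant="",
        pair=series.pair,
        carrier_band=series.carrier_band,
        envelope_band=series.envelope_band,
        condition=condition,
        m_psi=float(np.median(series.values[mask])),
        n_samples=n_valid,
    )


def pairwise_mpsi(
    phases: dict[str, PhaseSeries],
    pairs: list[tuple[str, str]],
    intervals: list[ConditionInterval],
    conditions: list[str],
    participant: str = "",
) -> pd.DataFrame:
    """M_psi for every requested channel pair and condition, as a table.

    One row per (pair, condition); any pair that cannot be computed raises
    rather than being silently dropped.  Returns a DataFrame with the fixed
    column order of :data:`PAIR_TABLE_COLUMNS`.
    """
    rows = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"pair ({a}, {b}) duplicates a channel")
        for ch in (a, b):
            if ch not in phases:
                raise KeyError(f"no phase series for channel {ch!r}")
        series = psi(phases[a], phases[b])
        for condition in conditions:
            pc = m_psi(series, intervals, condition)
            rows.append(
                {
                    "participant": participant,
                    "channel_a": a,
                    "channel_b": b,
                    "carrier_band": pc.carrier_band,
                    "envelope_band": pc.envelope_band,
                    "condition": condition,
                    "m_psi": pc.m_psi,
                    "n_samples": pc.n_samples,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)


def save_pair_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=PAIR_TABLE_COLUMNS)


def load_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
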