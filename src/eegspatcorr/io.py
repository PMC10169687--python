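"""Recordings, condition intervals and participant metadata: containers and I/O.

On-disk layout (one recording per file stem, BIDS-flavoured)::

    <stem>_eeg.npz        data (channels x samples), fs, channel labels
    <stem>_events.tsv     onset / duration / trial_type
    participants.tsv      participant_id / bdi / clinical   (cohort level)

EDF files are read through mne (optional path); a wide TSV format is
available for tiny, human-readable fixtures.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage

logger = logging.getLogger(__name__)

EYES_CLOSED = "eyes_closed"
EYES_OPEN = "eyes_open"
CONDITIONS = (EYES_CLOSED, EYES_OPEN)

#: trial_type spellings accepted by load_events (case-insensitive)
_TRIAL_TYPE_ALIASES = {
    "ec": EYES_CLOSED,
    "eyes_closed": EYES_CLOSED,
    "eyes closed": EYES_CLOSED,
    "closed": EYES_CLOSED,
    "eo": EYES_OPEN,
    "eyes_open": EYES_OPEN,
    "eyes open": EYES_OPEN,
    "open": EYES_OPEN,
}


@dataclass(frozen=True)
class ConditionInterval:
    """A [start, end) span (seconds) of one resting condition."""

    start: float
    end: float
    condition: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class Recording:
    """A channels-by-samples signal matrix with its sampling rate and events.

    ``data`` is in scalp-potential units (uV) before the surface Laplacian and
    in CSD-like units afterwards (see ``reference_note``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    condition_intervals: list[ConditionInterval] = field(default_factory=list)
    reference_note: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows vs "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.data.shape[1] == 0:
            raise ValueError("recording holds no samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels are not unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        ivs = sorted(self.condition_intervals, key=lambda iv: iv.start)
        for iv in ivs:
            if iv.start < -1e-9 or iv.end > self.duration + 1e-9:
                raise ValueError(
                    f"interval ({iv.start}, {iv.end}) outside [0, {self.duration}]"
                )
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"overlapping intervals {a} and {b}")
        self.condition_intervals = ivs

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, labels: list[str]) -> "Recording":
        """Sub-recording with the given channels, in the given order."""
        missing = [lab for lab in labels if lab not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        idx = [self.channel_labels.index(lab) for lab in labels]
        return replace(self, data=self.data[idx], channel_labels=list(labels))


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: id, Beck Depression Inventory score, clinical status."""

    id: str
    bdi: int
    clinical: str = "not_interviewed"
    group: str = ""

    def __post_init__(self) -> None:
        if self.bdi < 0:
            raise ValueError("BDI score must be >= 0")
        if self.clinical not in ("cMDD", "pMDD", "None", "not_interviewed"):
            raise ValueError(f"unknown clinical status {self.clinical!r}")
        expected = classify_participant(self.bdi, self.clinical)
        if self.group == "":
            object.__setattr__(self, "group", expected)
        elif self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with bdi={self.bdi}, "
                f"clinical={self.clinical!r} (expected {expected!r})"
            )


def classify_participant(bdi: int, clinical: str = "not_interviewed") -> str:
    """Assign the study group from the BDI score and clinical-interview status.

    BDI <= 7 is Control; BDI >= 13 is the depressive-symptoms group, split by
    clinical interview into Depressive-cMDD (current MDD), Depressive-pMDD
    (past MDD) and Depressive-None (no current or past MDD diagnosis; this
    bucket also holds depressive participants who were not interviewed).
    Scores of 8-12 fall in the gap between the two published thresholds and
    are returned as Unclassified.
    """
    if bdi < 0:
        raise ValueError("BDI score must be >= 0")
    if bdi <= 7:
        return "Control"
    if bdi >= 13:
        if clinical in ("cMDD", "pMDD"):
            return f"Depressive-{clinical}"
        return "Depressive-None"
    return "Unclassified"


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def load_events(path: str | Path) -> list[ConditionInterval]:
    """Read a BIDS-style events table (onset, duration, trial_type; TSV).

    Unknown trial types are skipped with a warning.  Overlapping or adjacent
    intervals of the same condition are merged; overlapping intervals of
    different conditions raise.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    intervals: list[ConditionInterval] = []
    for _, row in df.iterrows():
        cond = _TRIAL_TYPE_ALIASES.get(str(row["trial_type"]).strip().lower())
        if cond is None:
            warnings.warn(
                f"ignoring unknown trial_type {row['trial_type']!r}", stacklevel=2
            )
            continue
        intervals.append(
            ConditionInterval(float(row["onset"]), float(row["onset"]) + float(row["duration"]), cond)
        )
    return merge_intervals(intervals)


def merge_intervals(intervals: list[ConditionInterval]) -> list[ConditionInterval]:
    """Sort, merge same-condition overlaps/adjacency, reject cross-condition overlap."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[ConditionInterval] = []
    for iv in ivs:
        if merged and iv.start < merged[-1].end - 1e-9:
            if iv.condition != merged[-1].condition:
                raise ValueError(
                    f"overlapping intervals of different conditions: "
                    f"{merged[-1]} vs {iv}"
                )
        if (
            merged
            and iv.condition == merged[-1].condition
            and iv.start <= merged[-1].end + 1e-9
        ):
            last = merged.pop()
            merged.append(
                ConditionInterval(last.start, max(last.end, iv.end), iv.condition)
            )
        else:
            merged.append(iv)
    return merged


def save_events(intervals: list[ConditionInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "onset": [iv.start for iv in intervals],
            "duration": [iv.length for iv in intervals],
            "trial_type": [iv.condition for iv in intervals],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def save_recording(recording: Recording, stem: str | Path) -> None:
    """Write ``<stem>_eeg.npz`` plus the sidecar ``<stem>_events.tsv``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        f"{stem}_eeg.npz",
        data=recording.data,
        fs=recording.fs,
        channel_labels=np.array(recording.channel_labels),
        reference_note=np.array(recording.reference_note),
    )
    save_events(recording.condition_intervals, f"{stem}_events.tsv")


def load_recording(
    path: str | Path,
    format: str = "npz",
    montage: Montage | None = None,
) -> Recording:
    """Load a recording from disk.

    ``format``: ``npz`` (internal; ``path`` is the stem used by
    :func:`save_recording`), ``edf`` (via mne; EOG channels are dropped), or
    ``tsv`` (wide table, one column per channel, ``# fs=<Hz>`` header line).

    If ``montage`` is given, every montage channel must be present; missing
    channels raise with the explicit list of absentees.
    """
    if format == "npz":
        rec = _load_npz(Path(path))
    elif format == "edf":
        rec = _load_edf(Path(path))
    elif format == "tsv":
        rec = _load_tsv(Path(path))
    else:
        raise ValueError(f"unknown format {format!r}")

    if montage is not None:
        have = {c.lower() for c in rec.channel_labels}
        absent = [c for c in montage.channels if c.lower() not in have]
        if absent:
            raise ValueError(f"recording is missing montage channels: {absent}")
    return rec


def _load_npz(stem: Path) -> Recording:
    with np.load(f"{stem}_eeg.npz") as npz:
        data = npz["data"]
        fs = float(npz["fs"])
        labels = [str(x) for x in npz["channel_labels"]]
        note = str(npz["reference_note"])
    events_path = Path(f"{stem}_events.tsv")
    intervals = load_events(events_path) if events_path.exists() else []
    return Recording(data, fs, labels, intervals, note)


def _load_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    eog = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
    if eog:
        logger.info("dropping EOG channels %s", eog)
        raw.drop_channels(eog)
    data = raw.get_data() * 1e6  # mne returns volts; keep uV
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _load_tsv(path: Path) -> Recording:
    fs = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1])
    if fs is None:
        raise ValueError("tsv recording must start with a '# fs=<Hz>' line")
    df = pd.read_csv(path, sep="\t", comment="#")
    return Recording(df.to_numpy().T, fs, list(df.columns))


def _save_tsv(recording: Recording, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs}\n")
        pd.DataFrame(
            recording.data.T, columns=recording.channel_labels
        ).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------


def save_participants(records: list[ParticipantRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.id for r in records],
            "bdi": [r.bdi for r in records],
            "clinical": [r.clinical for r in records],
            "group": [r.group for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def load_participants(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            ParticipantRecord(
                id=str(row["participant_id"]),
                bdi=int(row["bdi"]),
                clinical=str(row.get("clinical", "not_interviewed")),
            )
        )
    return records
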