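"""Amplitude envelopes of band-limited oscillations and the instantaneous
phase of their infraslow / slow fluctuations.

The envelope is |Hilbert analytic signal| of the band-passed EEG.  Its
infraslow (0.05-0.1 Hz) or slow (0.1-1 Hz) component is isolated with the
same FIR design rule as the carrier bands; because at the raw 500 Hz rate
that rule yields a 70001-tap filter no realistic record can accommodate,
the envelope is first anti-aliased and decimated (default 10 Hz), all of
its sub-1 Hz content being far below the decimated Nyquist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import design_bandpass, filtfilt_zero_phase, rule_n_taps

__all__ = [
    "ENVELOPE_BANDS",
    "EnvelopeSeries",
    "PhaseSeries",
    "analytic_envelope",
    "envelope_band_phase",
]

#: Envelope fluctuation bands (Hz).
ENVELOPE_BANDS: dict[str, tuple[float, float]] = {
    "infraslow": (0.05, 0.1),
    "slow": (0.1, 1.0),
}


@dataclass
class EnvelopeSeries:
    """Nonnegative amplitude envelope of one channel's band-limited oscillation."""

    values: np.ndarray
    fs: float
    channel: str = ""
    carrier_band: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians, (-pi, pi]) of a filtered envelope fluctuation.

    ``valid`` masks out the filter-transient margins (half the filter length at
    each end); ``low_amplitude`` flags samples whose fluctuation amplitude is
    below 1% of the series s.d. (phase poorly defined there; such samples are
    still included in downstream medians but the flag enables sensitivity
    analyses).
    """

    values: np.ndarray
    fs: float
    channel: str = ""
    carrier_band: str = ""
    envelope_band: str = "infraslow"
    valid: np.ndarray | None = None
    low_amplitude: np.ndarray | None = None
    fluctuation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values > np.pi + 1e-12) or np.any(self.values <= -np.pi - 1e-12):
            raise ValueError("phases must lie in (-pi, pi]")
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        if self.low_amplitude is None:
            self.low_amplitude = np.zeros(len(self.values), dtype=bool)


def analytic_envelope(
    x: np.ndarray, fs: float, channel: str = "", carrier_band: str = ""
) -> EnvelopeSeries:
    """|analytic signal| of an (already band-passed, zero-mean) signal."""
    env = np.abs(signal.hilbert(np.asarray(x, dtype=float)))
    return EnvelopeSeries(env, fs, channel=channel, carrier_band=carrier_band)


def decimate_envelope(env: EnvelopeSeries, target_fs: float) -> EnvelopeSeries:
    """Anti-aliased decimation of an envelope to ``target_fs``."""
    if env.fs == target_fs:
        return env
    if env.fs < target_fs:
        raise ValueError("cannot decimate upward")
    ratio = env.fs / target_fs
    down = int(round(ratio))
    if abs(ratio - down) > 1e-9:
        raise ValueError(
            f"fs ratio {env.fs}/{target_fs} is not an integer decimation factor"
        )
    vals = signal.resample_poly(env.values, 1, down)
    # the FIR anti-alias filter can produce tiny negative overshoot
    vals = np.maximum(vals, 0.0)
    return EnvelopeSeries(vals, target_fs, channel=env.channel, carrier_band=env.carrier_band)


def envelope_band_phase(
    env: EnvelopeSeries,
    envelope_band: str = "infraslow",
    decimate_to: float | None = 10.0,
    strict_length: bool = False,
) -> PhaseSeries:
    """Band-pass the envelope and return the Hilbert phase of the fluctuation.

    The FIR tap count follows the design rule at the working rate,
    ``7 * floor(fs / f_lo) + 1``.  When the record is too short for the
    rule-length filter (forward-backward filtering needs more than three
    filter lengths of data) the tap count is capped at ``(n - 1) // 3``
    with a warning, unless ``strict_length`` is set, in which case the
    minimum duration is reported instead.
    """
    if envelope_band not in ENVELOPE_BANDS:
        raise KeyError(f"unknown envelope band {envelope_band!r}")
    f_lo, f_hi = ENVELOPE_BANDS[envelope_band]

    if decimate_to is not None and decimate_to < env.fs:
        env = decimate_envelope(env, decimate_to)
    n = len(env.values)
    n_taps = rule_n_taps(f_lo, env.fs)
    max_taps = (n - 1) // 3
    if n_taps > max_taps:
        if strict_length:
            min_dur = (3 * n_taps + 1) / env.fs
            raise ValueError(
                f"envelope of {n / env.fs:.1f} s is too short for the "
                f"{n_taps}-tap {envelope_band} filter; need at least "
                f"{min_dur:.1f} s at {env.fs} Hz"
            )
        if max_taps < 21:
            raise ValueError(
                f"envelope of {n} samples is too short for {envelope_band} "
                f"filtering at {env.fs} Hz"
            )
        n_taps = max_taps if max_taps % 2 == 1 else max_taps - 1
        warnings.warn(
            f"capping {envelope_band} filter at {n_taps} taps "
            f"(record supports no more)",
            stacklevel=2,
        )

    _, coeffs = design_bandpass(f_lo, f_hi, env.fs, n_taps=n_taps)
    fluct = filtfilt_zero_phase(env.values, coeffs)
    analytic = signal.hilbert(fluct)
    phase = np.angle(analytic)

    valid = np.ones(n, dtype=bool)
    margin = n_taps // 2
    valid[:margin] = False
    valid[n - margin :] = False

    amp = np.abs(analytic)
    sd = float(np.std(fluct))
    env_scale = float(np.mean(env.values))
    if sd < 1e-4 * max(env_scale, np.finfo(float).tiny):
        # essentially constant envelope: only filter leakage remains, the
        # phase is meaningless everywhere
        low = np.ones(n, dtype=bool)
    else:
        low = amp < 0.01 * sd

    return PhaseSeries(
        phase,
        env.fs,
        channel=env.channel,
        carrier_band=env.carrier_band,
        envelope_band=envelope_band,
        valid=valid,
        low_amplitude=low,
        fluctuation=fluct,
    )
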