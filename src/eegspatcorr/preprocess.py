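"""Edge trimming, FIR band-pass design, zero-phase filtering, surface
Laplacian (spherical-spline current source density) and spectral QC.

The band-pass design reproduces the MATLAB ``fir1`` recipe used throughout
this analysis family: a Hamming-windowed linear-phase FIR of order
``7 * floor(fs / f_lo)`` with normalized cutoffs ``2 f / fs``, applied
forward-backward (``filtfilt``) for zero phase shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import signal

from .io import ConditionInterval, Recording
from .montage import Montage

__all__ = [
    "FilterSpec",
    "LaplacianParams",
    "trim_edges",
    "design_bandpass",
    "filtfilt_zero_phase",
    "surface_laplacian",
    "spectrum",
    "band_peak_check",
    "BAND_QC_FREQUENCIES",
]

#: Oscillation bands (Hz) used throughout the analysis.
CARRIER_BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (17.0, 25.0),
}

#: Central vs peripheral frequency ranges (Hz, inclusive) for the spectral QC.
BAND_QC_FREQUENCIES: dict[str, tuple[list[tuple[float, float]], list[tuple[float, float]]]] = {
    "theta": ([(4, 5)], [(3, 3), (6, 7)]),
    "alpha": ([(9, 11)], [(8, 8), (12, 12)]),
    "beta": ([(20, 22)], [(17, 19), (23, 25)]),
}


@dataclass(frozen=True)
class FilterSpec:
    """A Hamming-window FIR band-pass specification."""

    f_lo: float
    f_hi: float
    fs: float
    n_taps: int
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi < self.fs / 2:
            raise ValueError(
                f"need 0 < f_lo < f_hi < fs/2, got ({self.f_lo}, {self.f_hi}) at fs={self.fs}"
            )
        if self.n_taps < 3:
            raise ValueError("n_taps must be >= 3")


@dataclass(frozen=True)
class LaplacianParams:
    """Spherical-spline CSD parameters.

    m: spline flexibility (4 = standard for scalp EEG); lam: Tikhonov
    regularization of the G matrix; legendre_terms: truncation of the
    Legendre series defining the spline kernels.
    """

    m: int = 4
    lam: float = 1e-5
    legendre_terms: int = 50

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.legendre_terms < 20:
            raise ValueError("legendre_terms must be >= 20")


def trim_edges(recording: Recording, margin_s: float = 10.0) -> Recording:
    """Drop the first and last ``margin_s`` seconds (edge-artifact removal).

    Condition intervals are shifted and cropped consistently; intervals that
    fall entirely inside a trimmed margin are dropped.
    """
    if recording.duration <= 2 * margin_s:
        raise ValueError(
            f"recording of {recording.duration:.1f} s is too short to trim "
            f"{margin_s} s from each end"
        )
    n_margin = int(round(margin_s * recording.fs))
    data = recording.data[:, n_margin : recording.n_samples - n_margin]
    new_duration = data.shape[1] / recording.fs
    intervals = []
    for iv in recording.condition_intervals:
        start = max(iv.start - margin_s, 0.0)
        end = min(iv.end - margin_s, new_duration)
        if end - start > 1e-9:
            intervals.append(ConditionInterval(start, end, iv.condition))
    return replace(
        recording, data=data, condition_intervals=intervals
    )


def rule_n_taps(f_lo: float, fs: float) -> int:
    """Tap count of the design rule: order 7*floor(fs/f_lo), plus one."""
    if f_lo <= 0:
        raise ValueError("f_lo must be positive")
    # guard against float roundoff (500/0.05 must floor to 10000, not 9999)
    return 7 * math.floor(fs / f_lo + 1e-9) + 1


def design_bandpass(
    f_lo: float, f_hi: float, fs: float, n_taps: int | None = None
) -> tuple[FilterSpec, np.ndarray]:
    """Design the Hamming-window FIR band-pass.

    Without ``n_taps`` the order follows the rule ``7 * floor(fs / f_lo)``
    (1162 for the 3-7 Hz theta band at 500 Hz, i.e. 1163 coefficients).
    """
    if n_taps is None:
        n_taps = rule_n_taps(f_lo, fs)
    spec = FilterSpec(f_lo=f_lo, f_hi=f_hi, fs=fs, n_taps=n_taps)
    coeffs = signal.firwin(
        n_taps, [f_lo, f_hi], window="hamming", pass_zero=False, fs=fs
    )
    return spec, coeffs


def filtfilt_zero_phase(
    x: np.ndarray, coeffs: np.ndarray, padlen: int | None = None
) -> np.ndarray:
    """Forward-backward FIR filtering with odd-reflect edge padding.

    Matches ``filtfilt(b, 1, x)`` semantics (zero phase, squared magnitude
    response) but runs the convolutions in the FFT domain, which is what makes
    the ~1000-tap filters of the design rule tractable on long multichannel
    records.  ``x`` may be 1-D or (channels, samples).
    """
    x = np.asarray(x, dtype=float)
    n_taps = len(coeffs)
    n = x.shape[-1]
    if padlen is None:
        padlen = 3 * n_taps
    if n <= padlen:
        raise ValueError(
            f"signal of {n} samples is shorter than the padding requirement "
            f"({padlen} samples for {n_taps} taps); lengthen the data, raise "
            f"the low cutoff, or decimate first"
        )
    one_d = x.ndim == 1
    if one_d:
        x = x[None, :]

    # odd (antisymmetric) reflection, as in MATLAB/scipy filtfilt
    left = 2 * x[:, :1] - x[:, padlen:0:-1]
    right = 2 * x[:, -1:] - x[:, -2 : -padlen - 2 : -1]
    xp = np.concatenate([left, x, right], axis=1)

    fwd = signal.fftconvolve(xp, coeffs[None, :], mode="full", axes=1)
    bwd = signal.fftconvolve(fwd[:, ::-1], coeffs[None, :], mode="full", axes=1)[:, ::-1]
    # combined kernel b*reverse(b) is symmetric about n_taps-1: zero net delay
    start = padlen + (n_taps - 1)
    y = bwd[:, start : start + n]
    return y[0] if one_d else y


# ---------------------------------------------------------------------------
# surface Laplacian (spherical-spline CSD)
# ---------------------------------------------------------------------------


def _spline_kernels(
    cosang: np.ndarray, params: LaplacianParams
) -> tuple[np.ndarray, np.ndarray]:
    """G (potential) and H (CSD) spline kernel matrices on the unit sphere.

    Legendre series: g(x) = sum_n (2n+1) / (n(n+1))^m P_n(x) / 4pi and
    h(x) = sum_n (2n+1) / (n(n+1))^(m-1) P_n(x) / 4pi.
    """
    n = np.arange(1, params.legendre_terms + 1, dtype=float)
    cg = np.zeros(params.legendre_terms + 1)
    ch = np.zeros(params.legendre_terms + 1)
    cg[1:] = (2 * n + 1) / (n * (n + 1)) ** params.m / (4 * np.pi)
    ch[1:] = (2 * n + 1) / (n * (n + 1)) ** (params.m - 1) / (4 * np.pi)
    return npleg.legval(cosang, cg), npleg.legval(cosang, ch)


def laplacian_matrix(
    positions: np.ndarray, params: LaplacianParams = LaplacianParams()
) -> np.ndarray:
    """Dense CSD transform matrix L such that ``csd = L @ potentials``.

    ``positions``: (n_channels, 3) unit vectors.  The output is the spline
    surface Laplacian on the unit sphere (no head-radius rescaling; the
    scale cancels in phase-based statistics downstream).
    """
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    off = ~np.eye(len(positions), dtype=bool)
    if np.any(cosang[off] > 1 - 1e-10):
        raise ValueError("coincident electrode positions in montage")
    G, H = _spline_kernels(cosang, params)
    Gs = G + params.lam * np.eye(len(G))
    Ginv = np.linalg.inv(Gs)
    ones = np.ones(len(G))
    tc = Ginv @ ones
    sgi = float(ones @ tc)
    # spline coefficients d = (Ginv - Ginv 1 1' Ginv / sgi) v  with sum(d) = 0
    P = Ginv - np.outer(tc, tc) / sgi
    return H @ P


def surface_laplacian(
    recording: Recording,
    montage: Montage,
    params: LaplacianParams = LaplacianParams(),
) -> Recording:
    """Spherical-spline current-source-density transform of a recording.

    Reduces volume-conduction blur before spatial-correlation analysis.  A
    spatially constant potential maps to ~0; the transform is linear and
    equivariant under channel reordering.
    """
    missing = [c for c in recording.channel_labels if c not in montage.positions]
    if missing:
        raise ValueError(f"channels without montage positions: {missing}")
    pos = montage.position_array(recording.channel_labels)
    L = laplacian_matrix(pos, params)
    return replace(
        recording,
        data=L @ recording.data,
        reference_note="spherical-spline CSD (unit sphere)",
    )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum (frequency grid in Hz, magnitude)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mag = np.abs(np.fft.rfft(x)) / x.size
    mag[1:] *= 2.0
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return freqs, mag


def band_peak_check(
    freqs: np.ndarray, magnitude: np.ndarray, band: str
) -> bool:
    """True iff the band's central frequencies carry more power than its edges.

    Central/peripheral ranges per band: theta 4-5 vs 3 and 6-7; alpha 9-11 vs
    8 and 12; beta 20-22 vs 17-19 and 23-25 (Hz).  Comparison is a strict
    inequality of mean magnitudes (a flat spectrum fails the check).
    """
    if band not in BAND_QC_FREQUENCIES:
        raise KeyError(f"unknown band {band!r}")
    central, peripheral = BAND_QC_FREQUENCIES[band]

    def mean_over(ranges: list[tuple[float, float]]) -> float:
        mask = np.zeros(len(freqs), dtype=bool)
        for lo, hi in ranges:
            mask |= (freqs >= lo - 0.5) & (freqs <= hi + 0.5)
        if not mask.any():
            raise ValueError(f"spectrum does not cover {ranges} Hz for band {band!r}")
        return float(np.mean(magnitude[mask]))

    return mean_over(central) > mean_over(peripheral)
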