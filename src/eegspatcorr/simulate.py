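"""Synthetic resting-state EEG with controllable infraslow envelope-phase
coupling.

Signal model, per channel c::

    x_c(t) = sum_bands [1 + m cos(2 pi f_env t + eta_bc(t))] cos(2 pi f_b t + phi_bc)
             + noise_scale * (1/f noise)

Each carrier band b is a sinusoid at the band's centre frequency whose
amplitude is modulated at an infraslow rate f_env; the modulation phase
eta_bc(t) is what couples channels.  eta decomposes into a shared latent
slow walk (common mode, cancelled by pairwise differencing), optional
region-level offset processes (used to plant region-pair coupling
deficits), and a per-channel offset process whose stationary spread
realizes the coupling concentration kappa: the phase difference of a
channel pair behaves like a von Mises variate of concentration kappa
(matched through the wrapped-Gaussian circular-moment correspondence,
variance 1/kappa; kappa = 0 degenerates to an unbounded slow walk, i.e. a
circularly uniform difference).  All offset processes are Ornstein-
Uhlenbeck walks whose decorrelation time is long compared with one
envelope period, so the instantaneous phase difference is a genuine slow
time series rather than a constant.

Cohorts attach a group label, a BDI score and (for depressive groups) a
planted coupling deficit to each participant; the defaults plant a partial
left frontal-left temporal theta deficit during eyes-closed rest in the
cMDD group and a left-right occipital alpha deficit during eyes-open rest
in the pMDD group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ConditionInterval, ParticipantRecord, Recording
from .montage import ANALYSIS_CHANNELS, DEFAULT_REGIONS

__all__ = [
    "CouplingSpec",
    "SimulationConfig",
    "CohortConfig",
    "alternating_schedule",
    "generate_recording",
    "generate_cohort",
    "participants_group_map",
]

DEFAULT_CARRIER_BANDS: tuple[tuple[str, float, float], ...] = (
    ("theta", 3.0, 7.0),
    ("alpha", 8.0, 12.0),
    ("beta", 17.0, 25.0),
)

#: kappa below this is treated as "no coupling" (uniform phase difference)
_KAPPA_FREE = 1e-3


@dataclass(frozen=True)
class CouplingSpec:
    """Envelope-phase coupling: one base concentration plus region-pair overrides.

    ``base_kappa`` sets the von Mises concentration of every channel pair's
    envelope-phase difference.  ``overrides`` maps
    ``(region_a, region_b, carrier_band, condition) -> kappa`` and plants a
    coupling deficit between two regions: a single shared offset process is
    added with opposite signs to the two regions, sized so their cross-pair
    difference has the override concentration, while pairs joining a target
    region to the rest of the scalp pick up a quarter of the added variance
    (the minimal collateral achievable when decoupling two regions that both
    remain coupled to everything else; phase-difference transitivity rules
    out a purely pairwise deficit).
    """

    base_kappa: float = 10.0
    overrides: dict[tuple[str, str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_kappa < 0:
            raise ValueError("base_kappa must be >= 0")
        for key, kappa in self.overrides.items():
            if kappa < 0:
                raise ValueError(f"override kappa for {key} must be >= 0")


def alternating_schedule(
    n_segments: int = 10, segment_s: float = 30.0, first: str = "eyes_closed"
) -> list[tuple[str, float]]:
    """Alternating eyes-closed / eyes-open segments (default 10 x 30 s)."""
    other = "eyes_open" if first == "eyes_closed" else "eyes_closed"
    return [(first if i % 2 == 0 else other, segment_s) for i in range(n_segments)]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    fs in Hz; duration in s; modulation_depth in [0, 1); envelope_freq in Hz
    (infraslow, 0.05-0.1); noise_exponent is the 1/f^a slope of the broadband
    floor; phase_tau / latent_tau are the decorrelation times (s) of the
    offset and latent phase processes.
    """

    fs: float = 500.0
    duration: float = 300.0
    channel_labels: tuple[str, ...] = ANALYSIS_CHANNELS
    carrier_bands: tuple[tuple[str, float, float], ...] = DEFAULT_CARRIER_BANDS
    envelope_freq: float = 0.07
    modulation_depth: float = 0.5
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    noise_exponent: float = 1.0
    noise_scale: float = 0.5
    condition_schedule: list[tuple[str, float]] = field(
        default_factory=alternating_schedule
    )
    regions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    phase_tau: float = 30.0
    latent_tau: float = 120.0
    process_fs: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.modulation_depth < 1:
            raise ValueError("modulation_depth must lie in [0, 1)")
        if self.duration * self.envelope_freq < 3:
            raise ValueError(
                f"duration {self.duration} s holds fewer than 3 cycles of the "
                f"{self.envelope_freq} Hz envelope modulation"
            )
        total = sum(length for _, length in self.condition_schedule)
        if abs(total - self.duration) > 1e-6:
            raise ValueError(
                f"condition schedule covers {total} s but duration is "
                f"{self.duration} s; segments must tile [0, duration]"
            )

    @property
    def intervals(self) -> list[ConditionInterval]:
        out, t = [], 0.0
        for condition, length in self.condition_schedule:
            out.append(ConditionInterval(t, t + length, condition))
            t += length
        return out

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for condition, _ in self.condition_schedule:
            if condition not in seen:
                seen.append(condition)
        return seen


def _ou_process(rng, n: int, dt: float, tau: float, stat_sd: float) -> np.ndarray:
    """Ornstein-Uhlenbeck walk with stationary s.d. ``stat_sd``."""
    from scipy import signal as _signal

    alpha = np.exp(-dt / tau)
    inc_sd = stat_sd * np.sqrt(1 - alpha**2)
    shocks = np.empty(n)
    shocks[0] = rng.normal(0.0, stat_sd)
    shocks[1:] = rng.normal(0.0, inc_sd, size=n - 1)
    # AR(1): x[i] = alpha x[i-1] + shock[i]
    return _signal.lfilter([1.0], [1.0, -alpha], shocks)


def _free_walk(rng, n: int, dt: float, tau: float) -> np.ndarray:
    """Unbounded slow walk: circularly uniform once wrapped (kappa = 0)."""
    x = np.empty(n)
    x[0] = rng.uniform(-np.pi, np.pi)
    x[1:] = rng.normal(0.0, np.pi * np.sqrt(dt / tau), size=n - 1)
    return np.cumsum(x)


def _offset_process(rng, n: int, dt: float, tau: float, kappa: float) -> np.ndarray:
    """One channel/region offset whose pairwise difference has concentration kappa.

    Two independent copies differ with variance 2 * (1 / 2 kappa) = 1/kappa,
    the wrapped-Gaussian match of von Mises concentration kappa.
    """
    if kappa < _KAPPA_FREE:
        return _free_walk(rng, n, dt, tau)
    return _ou_process(rng, n, dt, tau, np.sqrt(1.0 / (2.0 * kappa)))


def _one_over_f_noise(rng, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance spectrally shaped noise (flat below 0.1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.maximum(freqs, 0.1) ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / np.std(x)


def generate_recording(
    config: SimulationConfig, seed: int | None = None
) -> Recording:
    """One synthetic multichannel recording; identical (config, seed) pairs
    produce bit-identical output."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (argument or config.seed)")
    rng = np.random.default_rng(seed)

    fs_env = config.process_fs
    n_env = int(round(config.duration * fs_env))
    dt = 1.0 / fs_env
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    t_env = np.arange(n_env) / fs_env
    channels = list(config.channel_labels)
    conditions = config.conditions
    channel_region = {
        ch: region
        for region, chans in config.regions.items()
        for ch in chans
    }

    # envelope phase eta[band][channel] at the process rate, stitched over
    # the condition schedule
    band_names = [b[0] for b in config.carrier_bands]
    eta: dict[str, np.ndarray] = {}
    for band in band_names:
        per_condition: dict[str, np.ndarray] = {}
        for condition in conditions:
            latent = _free_walk(rng, n_env, dt, config.latent_tau)
            region_offsets: dict[str, np.ndarray] = {}
            for (ra, rb, ob, oc), kappa in config.coupling.overrides.items():
                if ob != band or oc != condition:
                    continue
                for region in (ra, rb):
                    if region not in config.regions:
                        raise KeyError(f"override names unknown region {region!r}")
                # antisymmetric shared process: the target-pair difference is
                # 2w (variance 1/kappa) while collateral pairs see only w
                if kappa < _KAPPA_FREE:
                    w = 0.5 * _free_walk(rng, n_env, dt, config.phase_tau)
                else:
                    w = _ou_process(
                        rng, n_env, dt, config.phase_tau, np.sqrt(1.0 / (4.0 * kappa))
                    )
                for region, sign in ((ra, 1.0), (rb, -1.0)):
                    if region in region_offsets:
                        region_offsets[region] = region_offsets[region] + sign * w
                    else:
                        region_offsets[region] = sign * w
            block = np.empty((len(channels), n_env))
            for i, ch in enumerate(channels):
                delta = _offset_process(
                    rng, n_env, dt, config.phase_tau, config.coupling.base_kappa
                )
                block[i] = latent + delta
                region = channel_region.get(ch)
                if region in region_offsets:
                    block[i] += region_offsets[region]
            per_condition[condition] = block
        stitched = np.empty((len(channels), n_env))
        for iv in config.intervals:
            lo = int(round(iv.start * fs_env))
            hi = int(round(iv.end * fs_env))
            stitched[:, lo:hi] = per_condition[iv.condition][:, lo:hi]
        eta[band] = stitched

    data = np.zeros((len(channels), n))
    for band_name, f_lo, f_hi in config.carrier_bands:
        f_center = 0.5 * (f_lo + f_hi)
        for i, _ch in enumerate(channels):
            eta_full = np.interp(t, t_env, eta[band_name][i])
            env = 1.0 + config.modulation_depth * np.cos(
                2 * np.pi * config.envelope_freq * t + eta_full
            )
            phi = rng.uniform(0, 2 * np.pi)
            data[i] += env * np.cos(2 * np.pi * f_center * t + phi)
    if config.noise_scale > 0:
        for i in range(len(channels)):
            data[i] += config.noise_scale * _one_over_f_noise(
                rng, n, config.fs, config.noise_exponent
            )

    return Recording(
        data=data,
        fs=config.fs,
        channel_labels=channels,
        condition_intervals=config.intervals,
        reference_note="synthetic",
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: default planted deficits: (region_a, region_b, carrier_band, condition, kappa)
DEFAULT_EFFECT_MAP: dict[str, list[tuple[str, str, str, str, float]]] = {
    "cMDD": [("left_frontal", "left_temporal", "theta", "eyes_closed", 2.0)],
    "pMDD": [("left_occipital", "right_occipital", "alpha", "eyes_open", 2.0)],
}

DEFAULT_BDI_RANGES: dict[str, tuple[int, int]] = {
    "Control": (0, 7),
    "cMDD": (13, 36),
    "pMDD": (13, 36),
    "None": (13, 36),
}

_CLINICAL_FOR_GROUP = {
    "Control": "not_interviewed",
    "cMDD": "cMDD",
    "pMDD": "pMDD",
    "None": "None",
}


@dataclass
class CohortConfig:
    """A synthetic cohort: group sizes, planted deficits, BDI ranges, base
    recording parameters and a master seed."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"Control": 10, "cMDD": 5, "pMDD": 5, "None": 0}
    )
    effect_map: dict[str, list[tuple[str, str, str, str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EFFECT_MAP.items()}
    )
    bdi_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BDI_RANGES)
    )
    base: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_group) - set(_CLINICAL_FOR_GROUP)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        for group, (lo, hi) in self.bdi_ranges.items():
            if group == "Control" and hi > 7:
                raise ValueError("Control BDI range must stay <= 7")
            if group != "Control" and lo < 13:
                raise ValueError(f"{group} BDI range must start >= 13")
        for group, effects in self.effect_map.items():
            if effects and self.n_per_group.get(group, 0) == 0:
                warnings.warn(
                    f"effect configured for empty group {group!r}", stacklevel=2
                )


def generate_cohort(
    cohort: CohortConfig,
) -> list[tuple[ParticipantRecord, Recording]]:
    """Generate one recording per participant; a pure function of the config.

    Per-participant seeds are derived deterministically from the master seed
    via ``numpy.random.SeedSequence``.
    """
    master = np.random.SeedSequence(cohort.seed)
    out: list[tuple[ParticipantRecord, Recording]] = []
    idx = 0
    for group in ("Control", "cMDD", "pMDD", "None"):
        count = cohort.n_per_group.get(group, 0)
        for _ in range(count):
            child = master.spawn(1)[0]
            sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % 2**31)
            rng = np.random.default_rng(sub_seed)
            lo, hi = cohort.bdi_ranges[group]
            bdi = int(rng.integers(lo, hi + 1))
            record = ParticipantRecord(
                id=f"sub-{idx + 1:03d}",
                bdi=bdi,
                clinical=_CLINICAL_FOR_GROUP[group],
            )
            overrides = dict(cohort.base.coupling.overrides)
            for ra, rb, band, condition, kappa in cohort.effect_map.get(group, []):
                overrides[(ra, rb, band, condition)] = kappa
            config = replace(
                cohort.base,
                coupling=replace(cohort.base.coupling, overrides=overrides),
            )
            recording = generate_recording(config, seed=sub_seed + 1)
            out.append((record, recording))
            idx += 1
    return out


def participants_group_map(
    records: list[ParticipantRecord], short: bool = True
) -> dict[str, str]:
    """Map participant id -> group label (short: Control/cMDD/pMDD/None)."""
    out = {}
    for r in records:
        g = r.group
        if short and g.startswith("Depressive-"):
            g = g.split("-", 1)[1]
        out[r.id] = g
    return out
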