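"""Seeded synthetic EEG cohorts with group-distinct spectral and coupling
structure.

The generator emulates 2-4 minute, 500 Hz, 8-channel resting-state
recordings for three groups.  Each channel is a sum of independent
band-limited noise (one component per rhythm, weighted by the group's
band-power profile), shared band-limited sources that couple channel sets
(coupling lowers the RWE between the members because they come to share the
same spectral energy distribution), a 1/f background, a common-mode powerline
sine, a random per-channel linear drift and a DC offset -- so every
preprocessing stage has something to remove.

Default group contrasts mirror the qualitative profiles the analysis relies
on: HC balanced with mild global coupling; MCI strongly coupled across
homologous cross-hemisphere pairs with weakened within-hemisphere coupling;
PPA strongly coupled within the left hemisphere with elevated delta and
reduced alpha power.  The ``effect`` dial interpolates every group toward the
HC profile ("none" makes the groups statistically identical, including a
common 60 Hz powerline, so classification must fall to chance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import CANONICAL_CHANNELS, GROUPS, RawRecording
from .spectral import BANDS

_BAND_RANGES = tuple(BANDS.values())

#: Channel sets a shared source can feed.
COUPLING_TEMPLATES: dict[str, tuple[str, ...]] = {
    "left": CANONICAL_CHANNELS[:4],
    "right": CANONICAL_CHANNELS[4:],
    "all": CANONICAL_CHANNELS,
    "F7-F8": ("F7", "F8"),
    "T7-T8": ("T7", "T8"),
    "CP3-CP4": ("CP3", "CP4"),
    "P5-P6": ("P5", "P6"),
}

EFFECT_SCALES = {"none": 0.0, "weak": 0.5, "default": 1.0, "strong": 1.5}

#: Per-group band-power weights (delta, theta, alpha, beta, gamma) and
#: coupling gains on each template.  HC doubles as the neutral profile the
#: effect dial interpolates toward.
_GROUP_BAND_WEIGHTS = {
    "HC": np.array([1.0, 0.8, 1.2, 0.6, 0.4]),
    "MCI": np.array([1.15, 0.85, 1.1, 0.6, 0.4]),
    "PPA": np.array([1.6, 0.9, 0.7, 0.6, 0.4]),
}
_GROUP_COUPLING = {
    "HC": {"left": 0.4, "right": 0.4, "all": 0.3},
    "MCI": {
        "left": 0.15,
        "right": 0.15,
        "all": 0.3,
        "F7-F8": 1.2,
        "T7-T8": 1.2,
        "CP3-CP4": 1.2,
        "P5-P6": 1.2,
    },
    "PPA": {"left": 1.4, "right": 0.8, "all": 0.2},
}
#: Source-study powerline frequencies (PPA recorded on a 50 Hz grid).
POWERLINE_BY_GROUP = {"HC": 60.0, "MCI": 60.0, "PPA": 50.0}


@dataclass
class GroupProfile:
    """Statistical recipe for one group's recordings."""

    band_weights: np.ndarray  # (8, 5) per-channel rhythm amplitudes
    coupling_gains: dict[str, float] = field(default_factory=dict)
    pink_amplitude: float = 1.0
    powerline_amplitude: float = 20.0
    powerline_hz: float = 50.0
    drift_amplitude: float = 40.0  # peak microvolt excursion over the recording
    dc_offset: float = 50.0

    def __post_init__(self) -> None:
        self.band_weights = np.atleast_2d(np.asarray(self.band_weights, dtype=float))
        if self.band_weights.shape != (8, 5):
            raise ValueError("band_weights must be an (8, 5) array")
        if np.any(self.band_weights < 0):
            raise ValueError("band weights must be non-negative")
        for name, gain in self.coupling_gains.items():
            if name not in COUPLING_TEMPLATES:
                raise ValueError(f"unknown coupling template {name!r}")
            if gain < 0:
                raise ValueError("coupling gains must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout; defaults mirror the source study (8 HC / 8 MCI / 14 PPA,
    2-4 minute recordings at 500 Hz)."""

    n_hc: int = 8
    n_mci: int = 8
    n_ppa: int = 14
    length_range_s: tuple[float, float] = (120.0, 240.0)
    rate: float = 500.0
    seed: int = 0
    effect: str = "default"

    def counts(self) -> dict[str, int]:
        return {"HC": self.n_hc, "MCI": self.n_mci, "PPA": self.n_ppa}


def _multiband_noise(
    weights: np.ndarray, n_samples: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Sum of independent band-limited noise components, one per rhythm, each
    normalized to (near-)unit RMS and scaled by its weight.

    Built in a single FFT pass: disjoint frequency bins of one white-noise
    draw are independent, so masking the bands of a shared spectrum is
    equivalent to summing separately drawn band-limited components.  The FFT
    runs at a padded fast length and the result is truncated.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    from scipy.fft import next_fast_len

    m = next_fast_len(int(n_samples))
    x = rng.standard_normal(m)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(m, d=1.0 / rate)
    power = np.abs(X) ** 2
    mult = np.full(f.size, 2.0)
    mult[0] = 1.0
    if m % 2 == 0:
        mult[-1] = 1.0
    scale = np.zeros_like(f)
    for (lo, hi), w in zip(_BAND_RANGES, np.asarray(weights, dtype=float)):
        if w == 0:
            continue
        mask = (f >= lo) & (f < hi)
        energy = (power[mask] * mult[mask]).sum() / m  # Parseval, time-domain energy
        if energy == 0:
            raise ValueError(f"band ({lo}, {hi}) contains no representable frequency bins")
        scale[mask] = w / np.sqrt(energy / m)
    return np.fft.irfft(X * scale, n=m)[:n_samples]


def band_limited_noise(
    band: tuple[float, float], n_samples: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-RMS noise whose spectrum is confined to ``band`` by
    hard spectral masking of white noise."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    lo, hi = band
    from scipy.fft import next_fast_len

    m = next_fast_len(int(n_samples))
    x = rng.standard_normal(m)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(m, d=1.0 / rate)
    X[(f < lo) | (f >= hi)] = 0.0
    y = np.fft.irfft(X, n=m)[:n_samples]
    rms = np.sqrt(np.mean(y * y))
    if rms == 0:
        raise ValueError(f"band {band} contains no representable frequency bins")
    return y / rms


def pink_noise(
    n_samples: int, rate: float, rng: np.random.Generator, exponent: float = 1.0
) -> np.ndarray:
    """1/f^exponent background noise, unit RMS, zero DC."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    from scipy.fft import next_fast_len

    m = next_fast_len(int(n_samples))
    x = rng.standard_normal(m)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(m, d=1.0 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    y = np.fft.irfft(X * shaping, n=m)[:n_samples]
    return y / np.sqrt(np.mean(y * y))


def default_profiles(effect: str = "default") -> dict[str, GroupProfile]:
    """Group profiles at a given effect size; "none" collapses all groups onto
    the HC profile (and a common powerline) so that no group signal remains."""
    if effect not in EFFECT_SCALES:
        raise ValueError(f"effect must be one of {list(EFFECT_SCALES)}")
    s = EFFECT_SCALES[effect]
    hc_w = _GROUP_BAND_WEIGHTS["HC"]
    profiles = {}
    for group in GROUPS:
        weights_1d = hc_w + s * (_GROUP_BAND_WEIGHTS[group] - hc_w)
        weights = np.tile(weights_1d, (8, 1))
        if group == "PPA" and s > 0:
            # alpha reduction is strongest over the left hemisphere
            weights[:4, 2] *= max(0.0, 1.0 - 0.25 * s)
        gains = {}
        for name in COUPLING_TEMPLATES:
            hc_gain = _GROUP_COUPLING["HC"].get(name, 0.0)
            g_gain = _GROUP_COUPLING[group].get(name, 0.0)
            gain = hc_gain + s * (g_gain - hc_gain)
            if gain > 0:
                gains[name] = gain
        powerline = 60.0 if s == 0 else POWERLINE_BY_GROUP[group]
        profiles[group] = GroupProfile(
            band_weights=weights, coupling_gains=gains, powerline_hz=powerline
        )
    return profiles


def generate_participant(
    profile: GroupProfile,
    length_s: float,
    rate: float,
    participant_id: str,
    group: str,
    rng: np.random.Generator,
) -> RawRecording:
    """Synthesize one recording from a group profile (draw order is fixed, so
    a seeded generator makes the output reproducible)."""
    n = int(round(length_s * rate))
    if n < 1:
        raise ValueError("recording length must be positive")
    data = np.zeros((8, n))
    for c in range(8):
        data[c] = _multiband_noise(profile.band_weights[c], n, rate, rng)
    mean_w = profile.band_weights.mean(axis=0)
    for name in COUPLING_TEMPLATES:  # fixed iteration order for determinism
        gain = profile.coupling_gains.get(name, 0.0)
        if gain <= 0:
            continue
        shared = _multiband_noise(mean_w, n, rate, rng)
        members = [CANONICAL_CHANNELS.index(ch) for ch in COUPLING_TEMPLATES[name]]
        data[members] += gain * shared
    for c in range(8):
        data[c] += profile.pink_amplitude * pink_noise(n, rate, rng)
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    data += profile.powerline_amplitude * np.sin(2 * np.pi * profile.powerline_hz * t + phase)
    ramp = np.linspace(0.0, 1.0, n)
    for c in range(8):
        data[c] += rng.uniform(-1, 1) * profile.drift_amplitude * ramp
        data[c] += rng.uniform(-1, 1) * profile.dc_offset
    data *= 10.0  # arbitrary microvolt scale; every feature is scale-invariant
    return RawRecording(
        participant_id=participant_id,
        group=group,
        data=data,
        rate=rate,
        channel_labels=CANONICAL_CHANNELS,
        powerline_hz=profile.powerline_hz,
    )


def generate_cohort(
    spec: CohortSpec | None = None, profiles: dict[str, GroupProfile] | None = None
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate the full cohort plus a participant -> group truth table."""
    spec = spec or CohortSpec()
    profiles = profiles or default_profiles(spec.effect)
    rng = np.random.default_rng(spec.seed)
    recordings: list[RawRecording] = []
    rows = []
    for group, count in spec.counts().items():
        for i in range(count):
            length = rng.uniform(*spec.length_range_s)
            pid = f"{group}{i + 1:02d}"
            recordings.append(
                generate_participant(profiles[group], length, spec.rate, pid, group, rng)
            )
            rows.append({"participant_id": pid, "group": group})
    return recordings, pd.DataFrame(rows)
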