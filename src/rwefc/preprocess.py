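"""Preprocessing chain for low-density resting-state EEG.

The chain, in order: channel selection, per-channel mean subtraction, a
Butterworth filter cascade (0.5 Hz high-pass, 100 Hz low-pass, band-stops at
the powerline frequency and its first two harmonics), an optional linear
detrend for channels whose residual drift survives the high-pass, common
average re-referencing, and segmentation into non-overlapping 8.192 s epochs.

All filters are applied forward-backward (zero phase) so that no relative
phase distortion is introduced across the channels later compared for
connectivity; the effective attenuation of each stage is therefore doubled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import (
    CANONICAL_CHANNELS,
    EPOCH_SECONDS,
    Epoch,
    RawRecording,
    epoch_samples,
)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth cascade parameters.

    ``order`` is the one-pass order of each filter (5 by default); zero-phase
    application doubles the effective order.  Band-stop filters are placed at
    the powerline frequency and its first two harmonics, each ``+/-
    bandstop_halfwidth_hz`` wide.
    """

    order: int = 5
    highpass_hz: float = 0.5
    lowpass_hz: float = 100.0
    bandstop_halfwidth_hz: float = 2.0
    n_harmonics: int = 3

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass_hz < lowpass_hz")

    def bandstop_centers(self, powerline_hz: float) -> tuple[float, ...]:
        return tuple(powerline_hz * (i + 1) for i in range(self.n_harmonics))


def select_channels(
    rec: RawRecording, wanted: tuple[str, ...] = CANONICAL_CHANNELS
) -> RawRecording:
    """Restrict a recording to ``wanted`` channels, reordered canonically."""
    indices = []
    for name in wanted:
        try:
            indices.append(rec.channel_labels.index(name))
        except ValueError:
            raise ValueError(f"channel {name} not found") from None
    return RawRecording(
        participant_id=rec.participant_id,
        group=rec.group,
        data=rec.data[indices],
        rate=rec.rate,
        channel_labels=tuple(wanted),
        powerline_hz=rec.powerline_hz,
    )


def subtract_channel_means(rec: RawRecording) -> RawRecording:
    """Remove each channel's DC offset (zero mean per electrode)."""
    return rec.with_data(rec.data - rec.data.mean(axis=1, keepdims=True))


def apply_filter_chain(
    rec: RawRecording, spec: FilterSpec | None = None, stage_log: list | None = None
) -> RawRecording:
    """High-pass, low-pass, then powerline band-stops, all zero-phase."""
    spec = spec or FilterSpec()
    nyq = rec.rate / 2.0
    if spec.lowpass_hz >= nyq:
        raise ValueError(f"low-pass cutoff {spec.lowpass_hz} Hz >= Nyquist {nyq} Hz")
    data = rec.data
    stages: list[tuple[str, np.ndarray]] = [
        ("highpass", sps.butter(spec.order, spec.highpass_hz / nyq, "highpass", output="sos")),
        ("lowpass", sps.butter(spec.order, spec.lowpass_hz / nyq, "lowpass", output="sos")),
    ]
    for center in spec.bandstop_centers(rec.powerline_hz):
        lo = center - spec.bandstop_halfwidth_hz
        hi = center + spec.bandstop_halfwidth_hz
        if hi >= nyq:  # harmonic outside the representable band
            continue
        stages.append(
            (f"bandstop@{center:g}", sps.butter(spec.order, [lo / nyq, hi / nyq], "bandstop", output="sos"))
        )
    for name, sos in stages:
        data = sps.sosfiltfilt(sos, data, axis=-1)
        if stage_log is not None:
            stage_log.append(name)
    return rec.with_data(data)


def _fit_line(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line fit per channel; returns (slope, intercept)."""
    n = x.shape[-1]
    t = np.arange(n, dtype=float)
    slope, intercept = np.polynomial.polynomial.polyfit(t, x.T, 1)[::-1]
    return np.atleast_1d(slope), np.atleast_1d(intercept)


def detrend_linear(rec: RawRecording) -> RawRecording:
    """Subtract the least-squares straight line from every channel."""
    return rec.with_data(sps.detrend(rec.data, axis=-1, type="linear"))


def has_linear_trend(channel: np.ndarray, threshold: float = 3.0) -> bool:
    """Trigger for the conditional detrend: the fitted line's total excursion
    over the channel exceeds ``threshold`` times the residual SD."""
    channel = np.asarray(channel, dtype=float)
    slope, intercept = _fit_line(channel[None, :])
    t = np.arange(channel.size, dtype=float)
    residual = channel - (slope[0] * t + intercept[0])
    resid_sd = residual.std()
    excursion = abs(slope[0]) * (channel.size - 1)
    return bool(excursion > threshold * resid_sd) if resid_sd > 0 else excursion > 0


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def segment_epochs(rec: RawRecording, epoch_s: float = EPOCH_SECONDS) -> list[Epoch]:
    """Cut the recording into consecutive non-overlapping epochs; the trailing
    partial epoch is discarded."""
    n_epoch = epoch_samples(rec.rate, epoch_s)
    n = rec.n_samples // n_epoch
    if n < 1:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one epoch ({n_epoch})"
        )
    return [
        Epoch(rec.participant_id, rec.group, i, rec.data[:, i * n_epoch : (i + 1) * n_epoch])
        for i in range(n)
    ]


def preprocess(
    rec: RawRecording,
    spec: FilterSpec | None = None,
    detrend: str = "auto",
    epoch_s: float = EPOCH_SECONDS,
    channels: tuple[str, ...] = CANONICAL_CHANNELS,
    stage_log: list | None = None,
) -> list[Epoch]:
    """Full chain: select -> demean -> filter -> (detrend) -> CAR -> epochs.

    ``detrend`` is ``"auto"`` (detrend only channels whose residual trend
    trips :func:`has_linear_trend`), ``"always"`` or ``"never"``.
    """
    if detrend not in ("auto", "always", "never"):
        raise ValueError("detrend must be 'auto', 'always' or 'never'")

    def log(stage: str) -> None:
        if stage_log is not None:
            stage_log.append(stage)

    rec = select_channels(rec, channels)
    log("select_channels")
    rec = subtract_channel_means(rec)
    log("subtract_channel_means")
    rec = apply_filter_chain(rec, spec, stage_log=stage_log)
    if detrend == "always":
        rec = detrend_linear(rec)
        log("detrend_linear")
    elif detrend == "auto":
        flagged = [i for i in range(rec.n_channels) if has_linear_trend(rec.data[i])]
        if flagged:
            data = rec.data.copy()
            data[flagged] = sps.detrend(data[flagged], axis=-1, type="linear")
            rec = rec.with_data(data)
            log("detrend_linear")
    rec = common_average_reference(rec)
    log("common_average_reference")
    epochs = segment_epochs(rec, epoch_s)
    log("segment_epochs")
    return epochs
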