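"""Filtering, re-referencing and windowing of EEG recordings.

The chain applied before decomposition is: zero-phase Butterworth band-pass
(0.5-45 Hz), IIR powerline notch (50 Hz), common average reference, and
segmentation into non-overlapping 8-second windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_eeg import Recording

__all__ = [
    "PreprocessConfig",
    "SegmentedRecording",
    "bandpass",
    "notch",
    "common_average_reference",
    "segment",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter and windowing parameters.

    hp_cutoff/lp_cutoff : band-pass corner frequencies in Hz.
    notch_freq : powerline frequency in Hz.
    window_seconds : analysis window length in seconds.
    filter_order : Butterworth order (applied forward-backward, zero phase).
    notch_quality : dimensionless Q of the IIR notch.
    """

    hp_cutoff: float = 0.5
    lp_cutoff: float = 45.0
    notch_freq: float = 50.0
    window_seconds: float = 8.0
    filter_order: int = 4
    notch_quality: float = 30.0

    def validate(self, fs: float) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff:
            raise ValueError("need 0 < hp_cutoff < lp_cutoff")
        if self.lp_cutoff >= fs / 2:
            raise ValueError(f"lp_cutoff {self.lp_cutoff} >= Nyquist {fs / 2}")
        if self.notch_freq >= fs / 2:
            raise ValueError(f"notch_freq {self.notch_freq} >= Nyquist {fs / 2}")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")


@dataclass
class SegmentedRecording:
    """Ordered non-overlapping windows cut from one recording."""

    subject_id: str
    label: str
    fs: float
    channels: list[str]
    segments: list[np.ndarray]  # each [n_channels x window_samples]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def window_samples(self) -> int:
        return self.segments[0].shape[1]


def bandpass(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Zero-phase Butterworth band-pass, per channel."""
    cfg.validate(rec.fs)
    sos = signal.butter(
        cfg.filter_order,
        [cfg.hp_cutoff, cfg.lp_cutoff],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=1))


def notch(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Zero-phase IIR notch at the powerline frequency."""
    cfg.validate(rec.fs)
    b, a = signal.iirnotch(cfg.notch_freq, cfg.notch_quality, fs=rec.fs)
    return rec.copy_with(signal.filtfilt(b, a, rec.data, axis=1))


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def segment(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> SegmentedRecording:
    """Cut into contiguous non-overlapping windows; partial tail discarded."""
    cfg.validate(rec.fs)
    w = int(round(cfg.window_seconds * rec.fs))
    if rec.n_samples < w:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{w}-sample window"
        )
    n = rec.n_samples // w
    segs = [rec.data[:, i * w : (i + 1) * w].copy() for i in range(n)]
    return SegmentedRecording(rec.subject_id, rec.label, rec.fs, list(rec.channels), segs)


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig = PreprocessConfig()
) -> SegmentedRecording:
    """Full chain: band-pass -> notch -> common average reference -> segment."""
    return segment(common_average_reference(notch(bandpass(rec, cfg), cfg)), cfg)
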