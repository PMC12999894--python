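"""Two-class synthetic multichannel EEG generator.

Each channel is a sum of amplitude-modulated narrowband oscillations in the
canonical delta (0.5-4), theta (4-8), alpha (8-13) and beta (13-30 Hz) bands
with random-walk phase, on top of 1/f-shaped background noise plus a white
floor.  The patient (SCH) class differs from controls by a multiplicative
band-power contrast: elevated delta/theta power, attenuated beta power, and
reduced oscillatory phase noise (more regular rhythms, i.e. lower broadband
complexity), optionally restricted to chosen lobes.  This reproduces the
qualitative class structure the classification pipeline assumes - low-band
energy dominance and reduced complexity in patients - without attempting to
mimic real EEG artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_eeg import (
    LOBES,
    MHRC16_CHANNELS,
    REPOD19_CHANNELS,
    MontageMap,
    Recording,
    write_edf,
    write_matrix,
)

__all__ = ["SynthConfig", "ClassEffect", "generate", "write_fixture"]

BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

# Baseline band amplitudes (uV) of an eyes-closed resting rhythm mixture.
BASE_AMPLITUDE = {"delta": 18.0, "theta": 12.0, "alpha": 10.0, "beta": 5.0}


@dataclass(frozen=True)
class ClassEffect:
    """Multiplicative SCH-vs-control contrast.

    delta_theta_power_ratio : SCH/control power multiplier in delta+theta.
    high_band_attenuation : SCH beta power multiplier.
    regularity_boost : SCH phase-noise multiplier (<1 = more regular).
    """

    delta_theta_power_ratio: float = 2.0
    high_band_attenuation: float = 0.5
    regularity_boost: float = 0.5

    def __post_init__(self) -> None:
        if min(self.delta_theta_power_ratio, self.high_band_attenuation,
               self.regularity_boost) <= 0:
            raise ValueError("effect multipliers must be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Study-shape and contrast parameters of the generator."""

    n_subjects_per_class: int = 10
    segments_per_subject: int = 4
    fs: float = 128.0
    montage: str | Sequence[str] = "mhrc16"
    window_seconds: float = 8.0
    effect: ClassEffect = field(default_factory=ClassEffect)
    affected_lobes: tuple = LOBES
    noise_exponent: float = 1.0
    noise_rms: float = 3.0
    white_rms: float = 1.0
    subject_gain_sd: float = 0.1
    seed: int = 0

    def channels(self) -> list[str]:
        if isinstance(self.montage, str):
            key = self.montage.lower()
            if key == "mhrc16":
                return list(MHRC16_CHANNELS)
            if key == "repod19":
                return list(REPOD19_CHANNELS)
            raise ValueError(f"unknown montage {self.montage!r}")
        return list(self.montage)

    def validate(self) -> None:
        if self.n_subjects_per_class < 1 or self.segments_per_subject < 1:
            raise ValueError("subject and segment counts must be positive")
        if self.fs / 2 <= BANDS["beta"][1]:
            raise ValueError(
                f"fs={self.fs} too low: Nyquist must exceed the beta band "
                f"({BANDS['beta'][1]} Hz)")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        for lobe in self.affected_lobes:
            if lobe not in LOBES:
                raise ValueError(f"unknown lobe {lobe!r}")


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / max(x.std(), 1e-12)


def _band_oscillation(rng: np.random.Generator, n: int, fs: float,
                      f_center: float, phase_noise_sd: float) -> np.ndarray:
    """Unit-amplitude narrowband oscillation: random-walk phase plus a slow
    positive amplitude envelope."""
    phase = 2 * np.pi * f_center / fs * np.arange(n)
    phase = phase + np.cumsum(rng.standard_normal(n) * phase_noise_sd)
    # Smooth envelope: heavily low-passed noise, mean 1, floored at 0.2.
    env_src = rng.standard_normal(n)
    kernel = np.hanning(int(fs * 2) | 1)
    kernel /= kernel.sum()
    env = np.convolve(env_src, kernel, mode="same")
    env = 1.0 + 0.3 * env / max(env.std(), 1e-12)
    env = np.clip(env, 0.2, None)
    return env * np.sin(phase)


def generate(cfg: SynthConfig = SynthConfig()) -> list[Recording]:
    """Deterministically generate labeled recordings for both classes.

    Each recording is exactly ``segments_per_subject`` analysis windows long.
    SCH band-power and regularity contrasts apply only to channels whose lobe
    is in ``cfg.affected_lobes``.
    """
    cfg.validate()
    channels = cfg.channels()
    montage = MontageMap()
    n = int(round(cfg.segments_per_subject * cfg.window_seconds * cfg.fs))
    rng = np.random.default_rng(cfg.seed)
    recordings: list[Recording] = []
    base_phase_noise = 0.10  # rad/sample random-walk step, control class
    for label in ("CONTROL", "SCH"):
        for s in range(cfg.n_subjects_per_class):
            sid = f"{label.lower()}_{s + 1:02d}"
            gains = {
                b: float(np.exp(rng.normal(0.0, cfg.subject_gain_sd)))
                for b in BANDS
            }
            data = np.empty((len(channels), n))
            for ci, ch in enumerate(channels):
                affected = (label == "SCH"
                            and montage.lobe(ch) in cfg.affected_lobes)
                x = np.zeros(n)
                for band, (lo, hi) in BANDS.items():
                    f_center = rng.uniform(lo + 0.1 * (hi - lo),
                                           hi - 0.1 * (hi - lo))
                    amp = BASE_AMPLITUDE[band] * gains[band]
                    phase_sd = base_phase_noise
                    if affected:
                        if band in ("delta", "theta"):
                            amp *= np.sqrt(cfg.effect.delta_theta_power_ratio)
                        elif band == "beta":
                            amp *= np.sqrt(cfg.effect.high_band_attenuation)
                        phase_sd *= cfg.effect.regularity_boost
                    x += amp * _band_oscillation(rng, n, cfg.fs, f_center,
                                                 phase_sd)
                x += cfg.noise_rms * _pink_noise(rng, n, cfg.fs,
                                                 cfg.noise_exponent)
                x += cfg.white_rms * rng.standard_normal(n)
                data[ci] = x
            recordings.append(Recording(sid, label, cfg.fs, list(channels),
                                        data))
    return recordings


def write_fixture(recordings: list[Recording], outdir: str | Path,
                  fmt: str = "csv") -> Path:
    """Write one file per recording plus a JSON manifest; returns its path."""
    if not recordings:
        raise ValueError("no recordings to write")
    if fmt not in ("csv", "edf"):
        raise ValueError(f"unknown format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.subject_id}.{fmt}"
        path = outdir / fname
        if fmt == "csv":
            write_matrix(path, rec)
        else:
            write_edf(path, rec)
        entries.append({
            "file": fname,
            "subject_id": rec.subject_id,
            "label": rec.label,
            "fs": rec.fs,
            "channels": rec.channels,
            "n_samples": rec.n_samples,
        })
    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"format": fmt, "recordings": entries}, fh, indent=2)
    return manifest
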