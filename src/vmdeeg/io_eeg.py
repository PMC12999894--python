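"""Reading and writing multichannel EEG recordings and 10-20 montage bookkeeping.

Two on-disk formats are supported: EDF (European Data Format, read through
:mod:`mne`, written by a minimal 16-bit EDF writer) and delimited-text sample
matrices with one header row of channel labels.  Channels are mapped onto the
five cortical lobes of the 10-20 system (frontal, central, parietal, temporal,
occipital) for lobe-wise analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "MontageMap",
    "DEFAULT_LOBE_MAP",
    "MHRC16_CHANNELS",
    "REPOD19_CHANNELS",
    "LOBES",
    "read_edf",
    "write_edf",
    "read_matrix",
    "write_matrix",
    "lobe_channels",
]

LOBES = ("frontal", "central", "parietal", "temporal", "occipital")

#: 16-channel adolescent resting-state montage (128 Hz acquisitions).
MHRC16_CHANNELS = [
    "O1", "O2", "P3", "P4", "Pz", "T5", "T6", "C3",
    "C4", "Cz", "T3", "T4", "F3", "F4", "F7", "F8",
]

#: 19-channel full 10-20 montage (250 Hz acquisitions).
REPOD19_CHANNELS = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]

# Midline electrodes join the lobe of their row (Fz->frontal, Cz->central,
# Pz->parietal), following standard 10-20 anatomy.
DEFAULT_LOBE_MAP: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal", "F3": "frontal", "F4": "frontal",
    "F7": "frontal", "F8": "frontal", "Fz": "frontal",
    "C3": "central", "C4": "central", "Cz": "central",
    "P3": "parietal", "P4": "parietal", "Pz": "parietal",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "O1": "occipital", "O2": "occipital",
}


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


def normalize_label(label: str) -> str:
    """Canonical 10-20 form: strip whitespace, title-case site letters.

    No regional aliasing (``T7`` is *not* rewritten to ``T3``); only case and
    whitespace are normalized, e.g. ``" fp1 "`` -> ``"Fp1"``, ``"PZ"`` -> ``"Pz"``.
    """
    s = label.strip()
    # 10-20 labels: site letters, then digits or a midline 'z'. Uppercase the
    # site (with 'Fp' cased conventionally), lowercase a trailing 'z'.
    head = s.rstrip("0123456789zZ")
    tail = s[len(head):].lower()
    head = head.upper()
    if head.startswith("FP"):
        head = "Fp" + head[2:]
    return head + tail


@dataclass
class Recording:
    """One labeled multichannel EEG recording.

    Attributes
    ----------
    subject_id : str
    label : str
        Binary class, ``"SCH"`` (patient) or ``"CONTROL"``.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered 10-20 channel labels.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    subject_id: str
    label: str
    fs: float
    channels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [n_channels x n_samples]")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.label not in ("SCH", "CONTROL"):
            raise ValueError(f"label must be 'SCH' or 'CONTROL', got {self.label!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains NaN/Inf samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(self.subject_id, self.label, self.fs, list(self.channels), data)


@dataclass
class MontageMap:
    """Mapping from channel label to cortical lobe."""

    lobe_of: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_LOBE_MAP))

    def __post_init__(self) -> None:
        bad = {ch: lb for ch, lb in self.lobe_of.items() if lb not in LOBES}
        if bad:
            raise ValueError(f"unknown lobes in montage map: {bad}")

    def lobe(self, channel: str) -> str:
        key = normalize_label(channel)
        if key not in self.lobe_of:
            raise KeyError(f"channel {channel!r} not in montage map")
        return self.lobe_of[key]

    @classmethod
    def from_file(cls, path: str | Path) -> "MontageMap":
        """Load a map from a YAML/JSON file of ``channel: lobe`` pairs."""
        import yaml

        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        return cls({normalize_label(k): v for k, v in mapping.items()})


def lobe_channels(
    montage: MontageMap, lobe: str, channels: Sequence[str]
) -> list[str]:
    """Channels of ``channels`` belonging to ``lobe``, in original order.

    Raises if ``lobe`` is not one of the five lobes or if any channel is
    missing from the montage map (never silently dropped).
    """
    if lobe not in LOBES:
        raise ValueError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
    missing = [c for c in channels if normalize_label(c) not in montage.lobe_of]
    if missing:
        raise KeyError(f"channels absent from montage map: {missing}")
    return [c for c in channels if montage.lobe_of[normalize_label(c)] == lobe]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, subject_id: str | None = None,
             label: str = "CONTROL") -> Recording:
    """Read an EDF file into a :class:`Recording` (data in microvolts).

    All channels must share one sampling rate; mixed-rate EDFs are rejected.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"malformed EDF file {path}: {exc}") from exc
    # mne resamples mixed-rate EDFs silently; detect from the raw header.
    n_per_rec = raw._raw_extras[0].get("n_samps")
    if n_per_rec is not None and len(set(int(n) for n in np.atleast_1d(n_per_rec))) > 1:
        raise FormatError(f"{path}: channels have mixed sampling rates")
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = [normalize_label(ch) for ch in raw.ch_names]
    return Recording(
        subject_id=subject_id or path.stem,
        label=label,
        fs=float(raw.info["sfreq"]),
        channels=channels,
        data=data,
    )


def write_edf(path: str | Path, rec: Recording,
              physical_max: float | None = None) -> None:
    """Write a :class:`Recording` as a minimal EDF file (16-bit samples).

    One data record per second; ``rec.fs`` must be a positive integer and the
    sample count a multiple of ``fs``; trailing samples are zero-padded into
    the final record.  Amplitudes are quantized onto ``[-physical_max,
    physical_max]`` microvolts (default: max absolute sample, rounded up).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    if physical_max is None:
        physical_max = float(np.ceil(max(np.abs(rec.data).max(), 1.0)))
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (2 * physical_max)

    ns = rec.n_channels
    hdr = bytearray()

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    hdr += f("0", 8)                               # version
    hdr += f(f"{rec.subject_id} {rec.label}", 80)  # patient id
    hdr += f("vmdeeg synthetic", 80)               # recording id
    hdr += f("01.01.00", 8) + f("00.00.00", 8)     # date, time
    hdr += f(str(256 * (ns + 1)), 8)               # header bytes
    hdr += f("", 44)                               # reserved
    hdr += f(str(n_rec), 8)                        # number of records
    hdr += f("1", 8)                               # record duration (s)
    hdr += f(str(ns), 4)                           # number of signals
    for ch in rec.channels:
        hdr += f(ch, 16)
    hdr += b"".join(f("", 80) for _ in range(ns))          # transducer
    hdr += b"".join(f("uV", 8) for _ in range(ns))         # physical dim
    hdr += b"".join(f(f"{-physical_max:g}", 8) for _ in range(ns))
    hdr += b"".join(f(f"{physical_max:g}", 8) for _ in range(ns))
    hdr += b"".join(f(str(dig_min), 8) for _ in range(ns))
    hdr += b"".join(f(str(dig_max), 8) for _ in range(ns))
    hdr += b"".join(f("", 80) for _ in range(ns))          # prefiltering
    hdr += b"".join(f(str(fs), 8) for _ in range(ns))      # samples/record
    hdr += b"".join(f("", 32) for _ in range(ns))          # reserved

    padded = np.zeros((rec.n_channels, n_rec * fs))
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(np.round(padded * scale), dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# Delimited text matrices
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    fs: float,
    channel_labels: Sequence[str] | None = None,
    *,
    subject_id: str | None = None,
    label: str = "CONTROL",
    samples_in_rows: bool = True,
    sep: str = ",",
) -> Recording:
    """Read a delimited numeric sample matrix with one header row of labels.

    With ``samples_in_rows`` (default) the file has one column per channel;
    otherwise one row per channel.  ``channel_labels`` overrides the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not samples_in_rows and channel_labels is None:
        raise FormatError(f"{path}: channel_labels required when "
                          "samples_in_rows=False")
    try:
        df = pd.read_csv(path, sep=sep, header=0 if samples_in_rows else None,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        elif df[col].isna().any():
            line = int(np.flatnonzero(df[col].isna().to_numpy())[0]) + 2
        else:
            continue
        raise FormatError(f"{path}: non-numeric or missing cell in column "
                          f"{col!r} at line {line}")
    mat = df.to_numpy(dtype=float)
    if samples_in_rows:
        mat = mat.T
        if channel_labels is None:
            channel_labels = [str(c) for c in df.columns]
    labels = [normalize_label(c) for c in channel_labels]
    return Recording(
        subject_id=subject_id or path.stem,
        label=label,
        fs=fs,
        channels=labels,
        data=mat,
    )


def write_matrix(path: str | Path, rec: Recording, *, sep: str = ",") -> None:
    """Write a recording as delimited text, samples in rows, labeled header."""
    df = pd.DataFrame(rec.data.T, columns=rec.channels)
    df.to_csv(path, sep=sep, index=False)


def write_manifest(path: str | Path, entries: Iterable[dict]) -> None:
    with open(path, "w") as fh:
        json.dump(list(entries), fh, indent=2)
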