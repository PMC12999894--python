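"""Model-ready feature tables: label/subject bookkeeping, lobe subsetting,
and leakage-safe per-fold normalization."""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .io_eeg import LOBES, MontageMap, normalize_label

__all__ = [
    "FeatureTable",
    "subset_lobe",
    "fit_normalizer",
    "apply_normalizer",
    "channel_of_feature_name",
]

_NAME_RE = re.compile(r"^CH(?P<channel>.+)_IMF(?P<imf>\d+)_(?P<feat>\w+)$")


def channel_of_feature_name(name: str) -> str:
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"feature name {name!r} does not follow "
                         "CH<label>_IMF<k>_<feature>")
    return m.group("channel")


@dataclass
class FeatureTable:
    """Rows = segments, columns = channel x IMF x feature.

    y uses 1 for the patient (SCH) class and 0 for controls.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    feature_names: list[str]
    segment_index: np.ndarray | None = None  # window ordinal within subject

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.X.shape[0]
        if self.segment_index is None:
            # consecutive ordinal per subject, in row order
            counts: dict = {}
            idx = np.empty(n, dtype=int)
            for i, sid in enumerate(self.subject_ids):
                idx[i] = counts.get(sid, 0)
                counts[sid] = idx[i] + 1
            self.segment_index = idx
        else:
            self.segment_index = np.asarray(self.segment_index, dtype=int)
        if len(self.segment_index) != n:
            raise ValueError("segment_index must align row-wise")
        if not (len(self.y) == len(self.subject_ids) == n):
            raise ValueError("X, y and subject_ids must align row-wise")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @property
    def n_segments(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def channel_of_feature(self) -> list[str]:
        return [channel_of_feature_name(n) for n in self.feature_names]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", np.where(self.y == 1, "SCH", "CONTROL"))
        df.insert(0, "segment_index", self.segment_index)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def save(self, path: str | Path) -> None:
        """CSV table plus a JSON schema sidecar (<path>.schema.json)."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        schema = {
            "n_segments": int(self.n_segments),
            "n_features": int(self.n_features),
            "feature_names": self.feature_names,
            "positive_class": "SCH",
        }
        with open(path.with_suffix(path.suffix + ".schema.json"), "w") as fh:
            json.dump(schema, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta = ("subject_id", "segment_index", "label")
        names = [c for c in df.columns if c not in meta]
        return cls(
            X=df[names].to_numpy(dtype=float),
            y=(df["label"] == "SCH").to_numpy(dtype=int),
            subject_ids=df["subject_id"].to_numpy(),
            feature_names=names,
            segment_index=(df["segment_index"].to_numpy()
                           if "segment_index" in df else None),
        )


def subset_lobe(tab: FeatureTable, montage: MontageMap, lobe: str) -> FeatureTable:
    """Retain only columns whose channel belongs to ``lobe``."""
    if lobe not in LOBES:
        raise ValueError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
    keep = [
        i for i, ch in enumerate(tab.channel_of_feature)
        if montage.lobe(normalize_label(ch)) == lobe
    ]
    if not keep:
        raise ValueError(f"no channels of lobe {lobe!r} in this table")
    return FeatureTable(
        X=tab.X[:, keep],
        y=tab.y.copy(),
        subject_ids=tab.subject_ids.copy(),
        feature_names=[tab.feature_names[i] for i in keep],
        segment_index=tab.segment_index.copy(),
    )


def fit_normalizer(train_X: np.ndarray) -> StandardScaler:
    """Per-column z-score statistics from training rows only.

    Zero-variance columns are centered but not scaled (scale factor 1).
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ValueError("normalizer needs >= 2 training rows")
    return StandardScaler().fit(train_X)


def apply_normalizer(normalizer: StandardScaler, X: np.ndarray) -> np.ndarray:
    return normalizer.transform(np.asarray(X, dtype=float))
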