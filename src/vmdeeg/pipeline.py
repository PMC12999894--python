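"""End-to-end glue: recordings -> preprocessing -> VMD -> feature table."""

from __future__ import annotations

import numpy as np

from .dataset import FeatureTable
from .features import EntropyParams, extract_features
from .io_eeg import Recording
from .preprocess import PreprocessConfig, preprocess_recording
from .vmd import VMDConfig, decompose_segment

__all__ = ["extract_feature_table"]


def extract_feature_table(
    recordings: list[Recording],
    pre: PreprocessConfig = PreprocessConfig(),
    vmd: VMDConfig = VMDConfig(),
    entropy: EntropyParams = EntropyParams(),
) -> FeatureTable:
    """Run the full feature pipeline over labeled recordings.

    Every recording is band-passed, notched, re-referenced and windowed; each
    window's channels are decomposed into ``vmd.K`` modes and summarized by
    the 8-feature battery.  One table row per window.
    """
    if not recordings:
        raise ValueError("no recordings given")
    rows, y, subject_ids = [], [], []
    names = None
    for rec in recordings:
        segs = preprocess_recording(rec, pre)
        for seg in segs.segments:
            res = decompose_segment(seg, rec.fs, vmd, channels=rec.channels)
            vals, nm = extract_features(res, rec.fs, entropy,
                                        channels=rec.channels)
            if names is None:
                names = nm
            elif nm != names:
                raise ValueError("inconsistent channel sets across recordings")
            rows.append(vals)
            y.append(1 if rec.label == "SCH" else 0)
            subject_ids.append(rec.subject_id)
    return FeatureTable(
        X=np.vstack(rows),
        y=np.asarray(y),
        subject_ids=np.asarray(subject_ids),
        feature_names=list(names),
    )
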