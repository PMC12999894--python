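import numpy as np
import pytest

from vmdeeg import Recording, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng):
    """60 s, 3 channels at 128 Hz of mixed narrowband + noise content."""
    fs = 128.0
    t = np.arange(0, 60, 1 / fs)
    data = np.vstack([
        10 * np.sin(2 * np.pi * 10 * t) + rng.standard_normal(t.size),
        5 * np.sin(2 * np.pi * 6 * t + 1.0) + rng.standard_normal(t.size),
        3 * np.sin(2 * np.pi * 21 * t + 2.0) + rng.standard_normal(t.size),
    ])
    return Recording("s01", "CONTROL", fs, ["F3", "C3", "O1"], data)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2+2 subjects, 2 segments each, 4 channels: fast end-to-end material."""
    cfg = SynthConfig(n_subjects_per_class=2, segments_per_subject=2,
                      montage=["F3", "F4", "C3", "O1"], seed=42)
    return generate(cfg)


def make_feature_table(n_subjects_per_class=4, segments_per_subject=5,
                       channels=("F3", "C3", "P3", "T3", "O1"), K=2,
                       effect=1.5, informative_channels=None, seed=0):
    """Directly synthesized FeatureTable (no signal pipeline): Gaussian
    features with a class shift on the informative channels' columns."""
    from vmdeeg.dataset import FeatureTable
    from vmdeeg.features import feature_names

    rng = np.random.default_rng(seed)
    names = feature_names(list(channels), K)
    n_feat = len(names)
    if informative_channels is None:
        informative_channels = channels
    informative = np.array([
        any(nm.startswith(f"CH{ch}_") for ch in informative_channels)
        for nm in names
    ])
    rows, y, sids = [], [], []
    for label in (0, 1):
        for s in range(n_subjects_per_class):
            sid = f"{'ctl' if label == 0 else 'sch'}{s}"
            subj_shift = rng.normal(0, 0.3, n_feat)
            for _ in range(segments_per_subject):
                x = rng.standard_normal(n_feat) + subj_shift
                if label == 1:
                    x = x + effect * informative
                rows.append(x)
                y.append(label)
                sids.append(sid)
    return FeatureTable(np.vstack(rows), np.array(y), np.array(sids), names)
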