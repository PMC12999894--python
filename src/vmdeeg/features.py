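"""Per-IMF feature battery: spectral, statistical, entropy and fractal measures.

Eight features are computed for every intrinsic mode function: mean Welch PSD,
skewness, kurtosis (Pearson, normal -> 3), differential entropy, approximate
entropy, sample entropy, Tsallis entropy and the Higuchi fractal dimension.
All logarithms are natural.  Undefined values (zero variance, empty template
matches) map to a 0.0 sentinel with a warning so downstream matrices stay
rectangular and finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._entropy_kernels import apen_phi_counts, sampen_pair_counts
from .vmd import VMDConfig, VMDResult, decompose_segment

__all__ = [
    "EntropyParams",
    "FEATURE_NAMES",
    "mean_psd",
    "skewness",
    "kurtosis",
    "diff_entropy",
    "approx_entropy",
    "sample_entropy",
    "tsallis_entropy",
    "higuchi_fd",
    "extract_features",
    "feature_names",
    "VMDFeatureExtractor",
]

#: Fixed per-IMF feature order.
FEATURE_NAMES = ("psd", "skew", "kurt", "de", "apen", "sampen", "tsallis", "hfd")


class SentinelWarning(UserWarning):
    """A feature was undefined on its input and replaced by the 0.0 sentinel."""


def _sentinel(reason: str) -> float:
    warnings.warn(f"undefined feature value ({reason}); using sentinel 0.0",
                  SentinelWarning, stacklevel=3)
    return 0.0


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the entropy and fractal estimators.

    m : embedding dimension for ApEn/SampEn.
    r : template tolerance as a fraction of the signal SD.
    q : Tsallis order (q != 1; Shannon entropy is the q -> 1 limit).
    n_bins : equal-width amplitude histogram bins for the Tsallis estimate.
    kmax : largest Higuchi delay.
    """

    m: int = 2
    r: float = 0.2
    q: float = 2.0
    n_bins: int = 64
    kmax: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.q <= 0 or self.q == 1:
            raise ValueError("q must be positive and != 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")


def mean_psd(x: np.ndarray, fs: float, band: tuple[float, float] = (0.5, 45.0)) -> float:
    """Mean Welch PSD (Hann window, nperseg=min(256, n), 50% overlap) over
    the EEG band, in uV^2/Hz."""
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError(f"signal too short for PSD ({x.size} < 64 samples)")
    nperseg = min(256, x.size)
    f, pxx = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError("no PSD bins inside the analysis band")
    return float(pxx[mask].mean())


def skewness(x: np.ndarray) -> float:
    """Standardized third central moment."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs >= 3 samples")
    if np.ptp(x) == 0 or np.var(x) == 0:
        return _sentinel("zero variance in skewness")
    return float(stats.skew(x, bias=True))


def kurtosis(x: np.ndarray) -> float:
    """Standardized fourth central moment, non-excess (normal -> 3)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("kurtosis needs >= 3 samples")
    if np.ptp(x) == 0 or np.var(x) == 0:
        return _sentinel("zero variance in kurtosis")
    return float(stats.kurtosis(x, fisher=False, bias=True))


def diff_entropy(x: np.ndarray) -> float:
    """Differential entropy under a Gaussian model: 0.5 * ln(2*pi*e*sigma^2),
    with sigma^2 the unbiased sample variance. Nats."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("differential entropy needs >= 2 samples")
    var = float(np.var(x, ddof=1))
    if var == 0:
        return _sentinel("zero variance in differential entropy")
    return 0.5 * float(np.log(2 * np.pi * np.e * var))


def approx_entropy(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy ApEn(m, r*sd, N) = Phi_m - Phi_{m+1}.

    Phi_m = (N-m+1)^-1 sum_i ln C_i^m with C_i^m the fraction of templates
    (self-match included) within Chebyshev radius r*sd of template i.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < p.m + 2:
        raise ValueError(f"ApEn needs >= m+2 = {p.m + 2} samples")
    radius = p.r * float(np.std(x))
    if radius == 0:
        return 0.0  # constant signal: all templates match at every length

    def phi(m: int) -> float:
        counts = apen_phi_counts(x, m, radius)
        return float(np.log(counts / (n - m + 1)).mean())

    return phi(p.m) - phi(p.m + 1)


def sample_entropy(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """Sample entropy -ln(A/B): A, B = template pair counts (i != j) within
    radius at lengths m+1 and m."""
    x = np.asarray(x, dtype=float)
    if x.size < p.m + 2:
        raise ValueError(f"SampEn needs >= m+2 = {p.m + 2} samples")
    radius = p.r * float(np.std(x))
    if radius == 0:
        return 0.0  # constant signal: A == B
    B, A = sampen_pair_counts(x, p.m, radius)
    if B == 0 or A == 0:
        return _sentinel("no template matches in sample entropy")
    return float(-np.log(A / B))


def tsallis_entropy(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """Tsallis entropy S_q = (1 - sum_i p_i^q) / (q - 1) from an equal-width
    amplitude histogram over [min(x), max(x)]."""
    x = np.asarray(x, dtype=float)
    if x.size < p.n_bins:
        raise ValueError(f"need >= n_bins = {p.n_bins} samples")
    if np.ptp(x) == 0:
        return 0.0  # single occupied bin
    hist, _ = np.histogram(x, bins=p.n_bins, range=(x.min(), x.max()))
    probs = hist / hist.sum()
    probs = probs[probs > 0]
    return float((1.0 - (probs ** p.q).sum()) / (p.q - 1.0))


def higuchi_fd(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """Higuchi fractal dimension: -slope of ln L(k) against ln k.

    L_a(k) is the normalized curve length of the subsampled series starting
    at offset a with stride k; L(k) averages over offsets a = 1..k.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 * p.kmax:
        raise ValueError(f"Higuchi FD needs >= 10*kmax = {10 * p.kmax} samples")
    if np.ptp(x) == 0:
        return _sentinel("zero variance in Higuchi FD")
    L = np.empty(p.kmax)
    for k in range(1, p.kmax + 1):
        lengths = []
        for a in range(k):
            idx = np.arange(a, n, k)
            nm = idx.size - 1  # floor((N-1-a)/k) intervals
            if nm < 1:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            lengths.append(dist * (n - 1) / (nm * k) / k)
        L[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, p.kmax + 1)
    slope = np.polyfit(np.log(k_arr), np.log(L), 1)[0]
    return float(-slope)


_FEATURE_FUNCS = {
    "psd": lambda x, fs, p: mean_psd(x, fs),
    "skew": lambda x, fs, p: skewness(x),
    "kurt": lambda x, fs, p: kurtosis(x),
    "de": lambda x, fs, p: diff_entropy(x),
    "apen": lambda x, fs, p: approx_entropy(x, p),
    "sampen": lambda x, fs, p: sample_entropy(x, p),
    "tsallis": lambda x, fs, p: tsallis_entropy(x, p),
    "hfd": lambda x, fs, p: higuchi_fd(x, p),
}


def feature_names(channels: list[str], K: int) -> list[str]:
    """Deterministic channel-major, IMF-then-feature ordered column names."""
    return [
        f"CH{ch}_IMF{k + 1}_{feat}"
        for ch in channels
        for k in range(K)
        for feat in FEATURE_NAMES
    ]


def extract_features(
    mode_results: list[VMDResult],
    fs: float,
    p: EntropyParams = EntropyParams(),
    channels: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Feature vector for one segment: channel-major, IMF index, then the
    fixed 8-feature order; length n_channels * K * 8."""
    if not mode_results:
        raise ValueError("no decomposition results given")
    K = mode_results[0].K
    if any(r.K != K for r in mode_results):
        raise ValueError("all channels must share the same K")
    if channels is None:
        channels = [f"ch{i}" for i in range(len(mode_results))]
    values = np.empty(len(mode_results) * K * len(FEATURE_NAMES))
    i = 0
    for res in mode_results:
        for k in range(K):
            imf = res.modes[k]
            for feat in FEATURE_NAMES:
                values[i] = _FEATURE_FUNCS[feat](imf, fs, p)
                i += 1
    return values, feature_names(channels, K)


class VMDFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping raw segments to the per-IMF feature battery.

    Stateless (``fit`` only validates); each input row of X is one segment of
    ``n_channels * window_samples`` flattened samples, transformed into
    ``n_channels * K * 8`` features.  Composes with sklearn pipelines.

    Parameters
    ----------
    fs : sampling rate of the segments, Hz.
    n_channels : channel count used to unflatten rows.
    vmd : VMDConfig for the per-channel decomposition.
    entropy : EntropyParams for the feature battery.
    channels : optional channel labels (defaults to ch0..chN-1).
    """

    def __init__(self, fs: float = 128.0, n_channels: int = 16,
                 vmd: VMDConfig | None = None,
                 entropy: EntropyParams | None = None,
                 channels: list[str] | None = None):
        self.fs = fs
        self.n_channels = n_channels
        self.vmd = vmd
        self.entropy = entropy
        self.channels = channels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % self.n_channels:
            raise ValueError("X rows must flatten n_channels x window_samples")
        self.n_features_in_ = X.shape[1]
        cfg = self.vmd or VMDConfig()
        self.feature_names_out_ = feature_names(
            self.channels or [f"ch{i}" for i in range(self.n_channels)], cfg.K
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        cfg = self.vmd or VMDConfig()
        p = self.entropy or EntropyParams()
        chans = self.channels or [f"ch{i}" for i in range(self.n_channels)]
        rows = []
        for row in X:
            seg = row.reshape(self.n_channels, -1)
            res = decompose_segment(seg, self.fs, cfg, channels=chans)
            vals, _ = extract_features(res, self.fs, p, channels=chans)
            rows.append(vals)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
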