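"""Feature battery tests: brute-force oracles for the template entropies,
closed forms for the differential/Tsallis entropies, known limits for the
Higuchi dimension, and bookkeeping of the channel x IMF x feature layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmdeeg.features import (
    FEATURE_NAMES,
    EntropyParams,
    SentinelWarning,
    approx_entropy,
    diff_entropy,
    extract_features,
    feature_names,
    higuchi_fd,
    kurtosis,
    mean_psd,
    sample_entropy,
    skewness,
    tsallis_entropy,
)
from vmdeeg.vmd import VMDConfig, decompose_segment

# ---------------------------------------------------------------------------
# Naive O(N^2) oracles, written directly from the definitions.
# ---------------------------------------------------------------------------


def apen_oracle(x, m, r_frac):
    x = np.asarray(x, float)
    n = x.size
    r = r_frac * np.std(x)

    def phi(mm):
        counts = []
        for i in range(n - mm + 1):
            c = 0
            for j in range(n - mm + 1):
                if max(abs(x[i + a] - x[j + a]) for a in range(mm)) <= r:
                    c += 1
            counts.append(c)
        return np.log(np.asarray(counts) / (n - mm + 1)).mean()

    return phi(m) - phi(m + 1)


def sampen_counts_oracle(x, m, r_frac):
    x = np.asarray(x, float)
    n = x.size
    r = r_frac * np.std(x)
    B = A = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + a] - x[j + a]) for a in range(m)) <= r:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return B, A


def sampen_oracle(x, m, r_frac):
    B, A = sampen_counts_oracle(x, m, r_frac)
    return float(-np.log(A / B))


class TestApproxEntropy:
    def test_constant_is_zero(self):
        assert approx_entropy(np.full(50, 3.3)) == 0.0

    def test_matches_oracle_on_periodic(self):
        x = np.array([1.0, 2.0] * 50)
        assert approx_entropy(x) == apen_oracle(x, 2, 0.2)

    @pytest.mark.parametrize("m,r", [(1, 0.1), (2, 0.2), (3, 0.35)])
    def test_matches_oracle_random(self, m, r):
        rng = np.random.default_rng(5)
        for n in (60, 120, 250):
            x = rng.standard_normal(n)
            p = EntropyParams(m=m, r=r)
            assert approx_entropy(x, p) == apen_oracle(x, m, r)

    def test_noise_more_irregular_than_sine(self):
        rng = np.random.default_rng(0)
        t = np.arange(1000)
        sine = np.sin(2 * np.pi * t / 25)
        noise = rng.standard_normal(1000) * sine.std()
        assert approx_entropy(noise) > approx_entropy(sine)


class TestSampleEntropy:
    def test_constant_is_zero(self):
        assert sample_entropy(np.full(30, -1.0)) == 0.0

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(200)
        assert sample_entropy(x) == sampen_oracle(x, 2, 0.2)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_affine_invariance(self, seed):
        """SampEn(x) == SampEn(-x) == SampEn(a + x): Chebyshev template
        matching only sees differences relative to the signal SD."""
        x = np.random.default_rng(seed).standard_normal(120)
        s = sample_entropy(x)
        assert sample_entropy(-x) == s
        assert sample_entropy(x + 17.0) == pytest.approx(s, abs=1e-12)

    def test_no_match_sentinel(self):
        # radius far below the smallest pairwise gap: B = 0, undefined
        x = np.random.default_rng(3).standard_normal(30)
        with pytest.warns(SentinelWarning):
            assert sample_entropy(x, EntropyParams(m=2, r=1e-12)) == 0.0

    def test_ordering_over_seeds(self):
        """White noise reads as less regular than a matched-variance sine."""
        t = np.arange(600)
        sine = np.sin(2 * np.pi * t / 30)
        se_noise, se_sine = [], []
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal(600) * sine.std()
            se_noise.append(sample_entropy(noise))
            se_sine.append(sample_entropy(sine))
        assert np.mean(se_noise) > np.mean(se_sine)


class TestKernelBackends:
    def test_numpy_path_equals_jitted_path(self):
        """The vectorized numpy fallback and the jitted kernels count the
        same template matches."""
        from vmdeeg._entropy_kernels import (
            _cheb_match_matrix,
            apen_phi_counts,
            sampen_pair_counts,
        )

        rng = np.random.default_rng(17)
        for n, m in [(80, 1), (150, 2), (150, 3)]:
            x = rng.standard_normal(n)
            r = 0.2 * np.std(x)
            np.testing.assert_array_equal(
                apen_phi_counts(x, m, r),
                _cheb_match_matrix(x, m, r).sum(axis=1))
            nt = n - m
            Mb = _cheb_match_matrix(x, m, r)[:nt, :nt]
            Ma = _cheb_match_matrix(x, m + 1, r)
            B, A = sampen_pair_counts(x, m, r)
            assert B == int(Mb.sum()) - nt
            assert A == int(Ma.sum()) - Ma.shape[0]


class TestMoments:
    def test_symmetric_skew_zero(self):
        assert skewness(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.0)

    def test_normal_kurtosis_three(self):
        x = np.random.default_rng(2).standard_normal(200_000)
        assert kurtosis(x) == pytest.approx(3.0, abs=0.1)

    def test_exponential_skew_two(self):
        x = np.random.default_rng(3).exponential(1.0, 100_000)
        assert skewness(x) == pytest.approx(2.0, abs=0.1)

    def test_zero_variance_sentinel(self):
        with pytest.warns(SentinelWarning):
            assert skewness(np.ones(10)) == 0.0
        with pytest.warns(SentinelWarning):
            assert kurtosis(np.ones(10)) == 0.0


class TestDifferentialEntropy:
    def test_unit_variance_closed_form(self):
        x = np.random.default_rng(0).standard_normal(4000)
        x = x / x.std(ddof=1)
        assert diff_entropy(x) == pytest.approx(0.5 * np.log(2 * np.pi * np.e),
                                                abs=1e-12)

    def test_inverse_of_closed_form_gives_one_nat(self):
        target_var = np.e ** 2 / (2 * np.pi * np.e)
        x = np.random.default_rng(1).standard_normal(4000)
        x = x * np.sqrt(target_var) / x.std(ddof=1)
        assert diff_entropy(x) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scaling_adds_log_c(self, c):
        x = np.random.default_rng(7).standard_normal(500)
        assert diff_entropy(c * x) == pytest.approx(
            diff_entropy(x) + np.log(c), abs=1e-9)


class TestTsallis:
    def test_uniform_closed_form(self):
        # near-uniform histogram over B bins at q=2 -> close to 1 - 1/B
        x = np.random.default_rng(0).random(200_000)
        assert tsallis_entropy(x) == pytest.approx(1 - 1 / 64, abs=1e-3)

    def test_constant_is_zero(self):
        assert tsallis_entropy(np.full(100, 2.5)) == 0.0

    def test_q_to_one_limit_is_shannon(self):
        x = np.random.default_rng(4).standard_normal(5000)
        hist, _ = np.histogram(x, bins=64, range=(x.min(), x.max()))
        p = hist / hist.sum()
        p = p[p > 0]
        shannon = float(-(p * np.log(p)).sum())
        got = tsallis_entropy(x, EntropyParams(q=1.0001))
        assert got == pytest.approx(shannon, abs=1e-3)


class TestHiguchi:
    def test_straight_line_dimension_one(self):
        assert higuchi_fd(np.arange(1000.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self):
        x = np.random.default_rng(11).standard_normal(5000)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.15)

    def test_affine_invariance(self):
        x = np.random.default_rng(12).standard_normal(2000)
        assert abs(higuchi_fd(x) - higuchi_fd(2 * x + 7)) < 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(50.0))


class TestMeanPsd:
    def test_parseval_on_sine(self):
        fs = 128.0
        t = np.arange(0, 8, 1 / fs)
        x = np.sin(2 * np.pi * 10 * t)
        from scipy.signal import welch

        f, pxx = welch(x, fs=fs, window="hann", nperseg=256, noverlap=128)
        band = (f >= 0.5) & (f <= 45)
        total = np.trapezoid(pxx[band], f[band])
        assert total == pytest.approx(x.var(), rel=0.01)  # ~0.5 uV^2
        assert mean_psd(x, fs) == pytest.approx(pxx[band].mean(), abs=1e-15)

    def test_zero_signal(self):
        assert mean_psd(np.zeros(1024), 128.0) == 0.0

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(1024)
        assert mean_psd(2 * x, 128.0) == pytest.approx(4 * mean_psd(x, 128.0),
                                                       rel=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            mean_psd(np.zeros(32), 128.0)


class TestExtractFeatures:
    def test_one_channel_one_mode(self, rng):
        res = decompose_segment(rng.standard_normal((1, 1024)), 128.0,
                                VMDConfig(K=1))
        vals, names = extract_features(res, 128.0, channels=["F3"])
        assert len(vals) == 8
        assert names == [f"CHF3_IMF1_{f}" for f in FEATURE_NAMES]
        assert np.isfinite(vals).all()

    def test_name_layout_channel_major(self):
        names = feature_names(["F3", "C3"], 2)
        assert names[0] == "CHF3_IMF1_psd"
        assert names[8] == "CHF3_IMF2_psd"
        assert names[16] == "CHC3_IMF1_psd"
        assert len(names) == 2 * 2 * 8
        assert len(set(names)) == len(names)

    def test_mixed_k_rejected(self, rng):
        seg = rng.standard_normal((2, 512))
        r1 = decompose_segment(seg[:1], 128.0, VMDConfig(K=2))
        r2 = decompose_segment(seg[1:], 128.0, VMDConfig(K=3))
        with pytest.raises(ValueError, match="same K"):
            extract_features(r1 + r2, 128.0)


class TestEntropyParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"m": 0}, {"r": 0.0}, {"q": 1.0}, {"q": -2.0}, {"n_bins": 1},
        {"kmax": 1},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            EntropyParams(**kwargs)
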