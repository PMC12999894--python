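# Methods

`vmdeeg` implements an EEG-based screening pipeline for schizophrenia
(SCH) versus control classification: preprocessing, variational mode
decomposition (VMD), a multi-domain feature battery per intrinsic mode
function (IMF), Bayesian-optimized classifiers, and leakage-aware evaluation
protocols. This note records the model, the parameters that matter, the
numerical choices, and the limits of what the synthetic experiments show.

## Signal model and preprocessing

Recordings are multichannel scalp EEG in microvolts on a 10–20 montage.
Two acquisition shapes are supported natively: a 16-channel montage at
128 Hz (O1, O2, P3, P4, Pz, T5, T6, C3, C4, Cz, T3, T4, F3, F4, F7, F8) and
the full 19-channel 10–20 montage at 250 Hz.

Preprocessing applies, in order: (1) zero-phase 4th-order Butterworth
band-pass 0.5–45 Hz (forward–backward `sosfiltfilt`, so the effective
attenuation is doubled and morphology is preserved); (2) zero-phase IIR
notch at 50 Hz with Q = 30; (3) common average reference; (4) segmentation
into non-overlapping 8-s windows, discarding any partial tail (never
zero-padding). The filter family, order and Q are package choices — standard
EEG practice — since only the cutoffs are externally constrained. Chain
order is fixed; re-running the chain on already-filtered data is nearly a
no-op for in-band content (content near the cutoffs is attenuated on every
pass, which is why the idempotence check uses a 2–40 Hz fixture).

## Variational mode decomposition

Each 8-s channel window is decomposed independently into K = 10 band-limited
modes u_k with center frequencies ω_k by minimizing the summed bandwidths of
the analytic-signal spectra subject to soft reconstruction, solved by the
canonical frequency-domain ADMM iteration:

    û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²)
    ω_k ← ∫₀^∞ ω |û_k(ω)|² dω / ∫₀^∞ |û_k(ω)|² dω
    λ̂  ← λ̂ + τ (f̂ − Σ_k û_k)

Defaults: α = 2000 (sensible range 2000–3000), τ = 0 (noise-tolerant, so
reconstruction is approximate), tolerance 1e-6 on the summed relative mode
change, at most 500 iterations. Center frequencies are initialized uniformly
over (0, fs/2) (deterministic; `zero` and seeded `random` initializations
are available), no DC mode is pinned, and modes are returned sorted by ω_k
(reported in Hz).

Numerical choices worth knowing:

- **Boundary handling.** The signal is mirror-extended by half its length on
  each side before the FFT and cropped after inversion. Mirror junctions
  carry a derivative kink, so narrowband components whose phase is steep at
  the window edge show ringing in the first/last few dozen samples; a
  cosine-phase tone (flat derivative at the edges) reconstructs with
  correlation > 0.999, a sine-phase tone ~0.997.
- **Offsets.** A constant offset is absorbed almost entirely by the lowest
  mode; because no mode is pinned at DC, a small residue (order 1e-3 RMS)
  redistributes into higher modes as their center frequencies re-seat.
- **Convergence.** The spectral residual typically rises once between
  iterations 1 and 2 while the ω_k re-seat, then decreases monotonically.
  A zero signal is a fixed point and converges in one iteration.

## Feature battery

Eight features per IMF, channel-major ordering
`CH{label}_IMF{k}_{feature}` with the fixed feature order
(psd, skew, kurt, de, apen, sampen, tsallis, hfd); 16 channels × 10 IMFs ×
8 features = 1,280 columns (19 channels → 1,520).

- **Mean PSD**: Welch (Hann, nperseg = min(256, n), 50% overlap), mean over
  0.5–45 Hz, in μV²/Hz.
- **Skewness / kurtosis**: standardized 3rd/4th central moments; kurtosis is
  non-excess (normal → 3). Downstream models are scale-insensitive after
  z-scoring, so the convention only matters for interpretation.
- **Differential entropy**: ½ ln(2πe σ²) with unbiased σ²; natural log (all
  logarithms in the package are natural).
- **Approximate / sample entropy**: Chebyshev template matching with
  m = 2 and radius r = 0.2·SD — the common EEG convention. ApEn includes
  self-matches (Φ_m − Φ_{m+1}); SampEn excludes them (−ln A/B) with both
  template populations restricted to the N−m starting points. Both are exact
  O(N²) counts (numba-jitted kernels with a pure-numpy fallback; both paths
  equal a brute-force oracle bit-for-bit on the counts).
- **Tsallis entropy**: order q = 2 over a 64-bin equal-width amplitude
  histogram; S_q = (1 − Σ p_i^q)/(q − 1); the q → 1 limit reproduces Shannon
  entropy, which the tests check.
- **Higuchi fractal dimension**: k_max = 10 (appropriate for 1–2k-sample
  windows); −slope of ln L(k) vs ln k. Line → 1, white noise → 2.

**Sentinels.** Undefined values (zero variance; no template matches) become
0.0 with a `SentinelWarning`, keeping matrices rectangular and finite; tests
assert when sentinels must fire.

## Classification and Bayesian optimization

The registry mirrors common EEG tool naming: tree presets (fine/medium/
coarse), LDA, logistic, Gaussian naive Bayes, SVMs (linear; inhomogeneous
polynomial degree 2/3 for "quadratic"/"cubic"; RBF with kernel scale
√d/4, √d, 4√d for fine/medium/coarse Gaussian), KNN presets, ensembles
(bagged/boosted trees, random-subspace KNN and discriminant) and small MLPs.

"Optimizable" models tune hyperparameters with a Gaussian-process surrogate
(Matérn ν = 2.5 on the unit-cube encoding of the search space) and the
expected-improvement acquisition (ξ = 0.01), maximized over a seeded
candidate set. The budget is 30 objective evaluations: 5 seeded Sobol
points, then EI proposals. The objective is mean misclassification over 10
stratified folds with fold-internal z-scoring. Ties in the trace resolve to
the earliest iteration; the whole search is deterministic given a seed.
Search bounds per family (e.g. SVM box constraint and kernel scale each
log-uniform on [1e-3, 1e3]; KNN k ∈ [1, 30] with metric and weighting
choices) are package choices documented in `models.SEARCH_SPACES`.

## Evaluation protocols

- **Segment-level 10-fold CV** (stratified, shuffled, seeded): normalizer
  fit per training fold, confusion counts pooled across folds. SCH is the
  positive class: Ac, SE, SP, PR, F1, ROC/AUC from decision scores.
  Precision is 0 (with a warning) if nothing is predicted positive.
- **Subject-wise LOOCV**: all segments of one subject held out per fold;
  the report carries per-subject segment accuracies, their unweighted mean,
  and sample SD. Per-subject accuracy is the fraction of that subject's
  segments classified correctly.
- **Leave-one-subject-per-class-out** (`paired_subject_cv`): one patient and
  one control held out per fold. Like LOOCV it is leakage-free; unlike
  LOOCV it keeps the training class ratio balanced. On near-chance problems
  plain LOOCV is biased *below* chance (the held-out subject's class is
  underrepresented in training), so the balanced variant is used for
  null-contrast calibration.
- **Lobe-wise sweep**: channels grouped into frontal {Fp1, Fp2, F3, F4, F7,
  F8, Fz}, central {C3, C4, Cz}, parietal {P3, P4, Pz}, temporal {T3, T4,
  T5, T6}, occipital {O1, O2} (midline electrodes join their row's lobe);
  every spec evaluated on every lobe subset with identical folds so
  comparisons are paired.
- **Paired comparison**: two-sided paired t-test with paired Cohen's d =
  mean(d)/SD(d); zero-variance nonzero differences yield NaN sentinels.

When a Bayesian-optimized model is evaluated by LOOCV, the default is to
optimize once on the full table and reuse that configuration in every fold
(tractability); hyperparameters are then not strictly subject-independent
even though the fitted weights are. Per-fold re-optimization is possible by
calling the optimizer inside a custom loop.

## Synthetic cohorts: what they emulate and what they do not

Each channel is a sum of amplitude-modulated narrowband oscillations
(random-walk phase, smooth positive envelope) in delta 0.5–4, theta 4–8,
alpha 8–13 and beta 13–30 Hz, plus 1/f background noise (exponent 1.0,
3 μV RMS) and a white floor (1 μV). Band amplitudes (18/12/10/5 μV) sketch
an eyes-closed resting rhythm mixture. Subjects get mild lognormal band-gain
jitter (SD 0.1) and subject-specific band peak frequencies, so recordings
carry a realistic subject fingerprint.

The patient class multiplies delta+theta power by 2.0, beta power by 0.5,
and phase-noise by 0.5 (more regular, i.e. lower complexity), optionally
restricted to chosen lobes. Effects are multiplicative on band power, and
a 5-point grid over the power ratio is recovered monotonically by the
low-mode PSD/differential-entropy features (Spearman ρ > 0.9).

What passing tests show: the pipeline detects planted band-power and
regularity contrasts of realistic magnitude under subject-independent
evaluation, and finds nothing when no contrast is planted. What they do not
show: performance on real EEG — the generator has no artifacts (blinks,
EMG), no nonstationarity beyond slow envelopes, no volume-conduction
correlation structure between channels, and its class contrast is cleaner
than clinical reality.

A consequence of the subject fingerprint worth emphasizing: under a *null*
class contrast, segment-level 10-fold CV still scores up to ~70% by
memorizing subjects — the leakage that motivates subject-wise protocols in
the first place. Null calibration therefore uses `paired_subject_cv` and
judges the mean over 5 seeded cohorts.

## Experiment sizes

The packaged experiments use desk-scale cohorts chosen once: the strong-
contrast study runs 10+10 subjects × 4 segments on the 16-channel montage at
128 Hz (80 segments × 1,280 features); null calibration runs 5+5 subjects ×
3 segments on a 6-channel montage across 5 seeds. The scripts' seeds derive
from a single `--seed` argument; identical seeds reproduce identical tables
and metrics bit-for-bit.

## Known limitations

- τ = 0 means modes do not exactly reconstruct the input; the residual is
  a diagnostic, not noise-free.
- EDF output is 16-bit; amplitudes round-trip only to the quantization step
  of the configured physical range. The writer requires integer sampling
  rates and pads the last record with zeros.
- The text-matrix reader assumes a delimited numeric layout with a label
  header row; acquisition-specific formats must be converted first.
- ApEn/SampEn are O(N²) per IMF; 8-s windows at 128–250 Hz are comfortable,
  but minute-long undivided windows would not be.
- The optimizer's categorical dimensions are embedded on a line segment for
  the GP, which is crude for many-valued categoricals; with ≤4 choices per
  dimension it has not been a practical problem.
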