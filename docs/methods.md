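# Methods

This note documents the models, conventions and numerical choices behind
swallowflow, and what the synthetic data can and cannot establish.

## Synthetic data model

No raw dual-axis accelerometry recordings from the protocol this package
analyses are publicly available, so the generator reproduces the protocol's
*structure* and the *feature-level statistics* of its reported effects, not
waveform physiology.

**Protocol.** Each synthetic participant records 17 sequences — every
stimulus × task combination twice plus a third water-discrete repetition —
each containing exactly four swallows with inter-swallow rest gaps
(discrete task: 2 s mean; sequential: 0.2 s mean, mimicking continuous
drinking), a 5 s lead-in before the first swallow, and one noise-only
baseline recording per session.

**Swallow waveform.** A biphasic burst envelope (two Gaussian lobes at 30%
and 62% of the swallow duration) modulates a low-frequency oscillation
(8–14 Hz fundamental plus a weaker 2.1× partial with random phases). A
quadratic asymmetry x → x − γx²/max|x| with γ = 0.8·(1 − skew_shape)
skews the amplitude distribution negative; lower `skew_shape` gives more
negative A-P skewness. The waveform is then mean-centred: a vibration
signal carries no net acceleration offset, and an uncentred offset would
ring through the acquisition highpass into the rest gaps. The S-I channel
mixes a 3-tap-smoothed copy of the shared source (fraction `coupling`,
default 0.6) with an independent oscillation under the same envelope.
Broadband white noise is added at RMS `noise_amplitude` relative to the
structured component. The waveform shape itself is a modelling choice;
only its feature-level consequences are asserted anywhere.

**Stimulus profiles.** Mean swallow durations are fixed to the published
per-task stimulus means (discrete 2.097/2.056/2.228/2.324 s, sequential
1.463/1.533/1.643/1.747 s for water/barium/nectar/honey). `noise_amplitude`
(0.34/0.26/0.18/0.13) decreases strictly with viscosity: it is the
regularity knob that makes entropy rate rise and Lempel-Ziv complexity fall
with viscosity, with separations large enough that these latent orderings
are resolvable at the study's sample size (17 participants), mirroring a
protocol in which those effects were statistically detectable. `skew_shape`
(0.25/0.24/0.45/0.55) makes the thickened juices less negatively skewed on
the A-P axis. Note the published discrete-task durations are *not* monotone
between water and barium (2.097 > 2.056 s); the defaults reproduce the
published values rather than forcing monotonicity.

**Participant effects.** Each participant draws an additive duration offset
(SD 0.3 s), and log-normal amplitude (SD 0.2) and noise (SD 0.1) scales,
applied to every swallow of the session. This blocking structure is what
makes the participant-blocked Friedman design meaningful. Within-participant
swallow durations vary with SD 0.15 s, truncated at 20% of the cell mean.

**Acquisition chain.** Input-referred sensor noise (SD 0.01) is added
first, then an AR(2) coloration (coefficients 0.6, −0.2), a 2nd-order
Butterworth bandpass (0.1 Hz to min(3 kHz, 0.99·Nyquist)) and a 10× gain.
Placing the sensor noise *before* the chain is deliberate: it is what makes
noise-only baseline recordings carry the chain's spectral signature, so
that AR models fitted to a baseline genuinely estimate (and their inverse
FIR filters cancel) the chain.

**What the generator does not emulate.** Real hyolaryngeal biomechanics,
sip-volume variation (absorbed into duration/amplitude variability),
swallow-internal nonstationarity beyond the envelope, inter-swallow
autocorrelation, artifacts (speech, head movement), or the absolute signal
scale (amplitudes are arbitrary units; every feature except the raw mean
and variance is scale-invariant by construction). Tests passing on this
generator show the *pipeline* is correct and adequately powered for
effects of the modelled size and structure — not that real recordings have
those effect sizes.

## Preprocessing conventions

- **Segmentation** is a simplified envelope-based stand-in for
  sequential fuzzy c-means detectors used with this kind of signal: windowed
  RMS of ap² + si² (window 0.1 s, 50% overlap), 2-cluster fuzzy c-means
  (m = 2) on the log envelope, runs of active windows merged and snapped to
  window edges, segments shorter than 0.3 s dropped, and at most
  `expected_count` highest-energy segments kept. Externally supplied
  boundary files replace it transparently, so manual annotations can be
  used with real data. Against generator ground truth it recovers
  essentially all swallows with Jaccard ≈ 0.9 in both tasks.
- **Inverse filtering**: modified-covariance (forward-backward least
  squares) AR fit of order 10 (configurable) per axis on the session
  baseline; whitening FIR taps [1, −a₁, …, −a_P]. Order selection is left
  to the user; order 10 comfortably covers the AR(2)-plus-bandpass default
  chain. Constant or rank-deficient baselines raise a degenerate-input
  error.
- **Denoising**: 10-level DWT, soft threshold
  T = (median|d₁|/0.6745)·√(2 ln n) — the universal threshold with a robust
  MAD noise estimate taken from the first-level detail coefficients; natural
  log; approximation band untouched. Signals shorter than 2^levels use one
  level per length-octave minus one.
- **Stage order** is fixed: segment → inverse FIR → denoise.
- All sample intervals are 0-based, half-open.

## Wavelet implementation

The discrete Meyer wavelet is an FIR truncation of the analytic Meyer
filter. The widely used 62-tap truncation reconstructs only to ~1e-2,
which would swamp the package's energy-conservation and pass-through
contracts, so swallowflow builds a 512-tap filter bank by frequency
sampling (max-abs reconstruction error ~2e-9); the name "dmey" resolves to
it throughout. Both the feature DWT and denoising use **periodized**
transforms: periodization keeps the transform orthogonal, conserves energy
exactly (the relative-energy features depend on it), keeps per-band
coefficient counts dyadic, and makes denoising a true projection (hence
idempotent once all detail coefficients are below threshold). Symmetric
extension was considered and rejected: with a 512-tap filter at 10 levels,
boundary extension inflates coarse-band coefficient counts and energy by
tens of percent, and the transform is no longer a projection. The feature
decomposition always uses the full 10 levels regardless of signal length,
so the 11-band feature identity is stable; for short signals the coarse
bands are boundary-dominated, which affects all stimuli alike.

## Feature conventions

- Entropies are in nats; ρ and λ are entropy *ratios*, so the base cancels.
- Pattern identity is exact symbol-tuple equality — equivalent to an
  injective base-Q integer coding of the quantized patterns without
  10³⁰-scale arithmetic.
- Quantization bins span min…max with the maximum clipped into the top bin;
  entropy features standardise first (a no-op for the binning, kept for
  fidelity to the construction), Lempel-Ziv quantizes the raw signal. Both
  are invariant to positive affine transforms.
- The Lempel-Ziv parser uses the exhaustive history with overlap: the
  search window for a candidate block ending at position i+l is
  s[0 : i+l−1]; an incomplete final block counts, so a constant sequence
  parses into exactly 2 blocks.
- Kurtosis is non-excess (Gaussian = 3). Autocorrelation uses the biased
  (divisor-n) estimator, guaranteeing |r| ≤ 1; the memory feature takes the
  first lag at or below 1/e without interpolation and returns the maximum
  lag if the threshold is never crossed.
- Constant-signal conventions: ρ = 1 (maximum regularity); λ, skewness,
  kurtosis, memory and R_XY(0) are recorded as missing (NaN) and ignored
  by the statistical stage's medians.
- ρ and λ need SE(L−1) at L = 10, so pattern entropies are computed for
  L = 9…30.
- The 30-feature vector always uses the fixed retained-band lists
  (A-P: a10…d7; S-I: a10…d6) so feature identity is stable across
  datasets; the empirical 95% cumulative-energy rule that motivates those
  lists is available separately (`truncate_bands`) as a calibration tool.

## Statistical stage

Cell medians (participant × stimulus) absorb unequal swallow counts and
outliers; participants with any empty cell are dropped per feature (with a
warning), and fewer than three complete participants is an error. The
Friedman test uses within-block midranks with tie correction against a
χ²₃ reference (scipy), with an explicit all-constant guard returning
(0, 1). Post-hoc comparisons are two-sided Wilcoxon rank-sum tests — exact
null distribution when the combined n ≤ 20 and there are no ties, normal
approximation with tie/continuity correction otherwise — Bonferroni-scaled
by the six stimulus pairs. No correction is applied *across* the 30
Friedman tests, matching the analysis this stage reproduces; the report
notes this. The unpaired rank-sum (rather than a paired test) is likewise
kept for fidelity.

## Problem sizes and reduced designs

All features are defined relative to the sampling rate, so tests and
simulation studies run at reduced rates (250–1000 Hz instead of 10 kHz);
the examples state the rate they use. Entropy-rate and complexity values at
these rates are smaller than at 10 kHz (less oversampling means fewer
repeated patterns), but every ordering property holds at both scales, and
the acceptance checks are deliberately ordering/range-based rather than
value-based for exactly this reason. Power and calibration studies use the
feature-level simulation path (`study.simulate_feature_table`): swallows are
generated directly and features extracted, skipping the
acquisition-plus-inverse-filter round trip (identity in expectation) and
segmentation (exact under ground truth). The full recording path —
assembly, acquisition chain, baseline AR fit, segmentation, denoising —
is exercised end-to-end by the pipeline tests and the CLI. The Friedman
type-I calibration simulates the null at the duration-draw level (all four
profiles identical), which is sufficient because only the distribution of
the block matrix matters to the test.

## Known limitations

- The segmenter is tuned to burst-plus-gap structure; heavily overlapping
  swallows (no envelope dip) merge, mirroring the exclusion of
  unsegmentable swallows in practice.
- Periodized wavelet transforms assume implicit circular continuation;
  segments whose endpoints differ grossly in level acquire small wrap
  artifacts in the coarse bands.
- The cross-entropy rate is computed at the same 10-level quantization as
  ρ; very short segments (n < 31) cannot provide the L = 30 window and
  raise an error rather than silently truncating the L range.
- The generator's stimulus effects are monotone in viscosity by design
  (except the published non-monotone discrete durations); it cannot be
  used to argue about the *shape* of real viscosity-response curves.
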