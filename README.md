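# swallowflow

Dual-axis swallowing-accelerometry analysis: synthetic signal generation,
swallow segmentation and conditioning, extraction of 30 time and
time-frequency features, and nonparametric testing for stimulus effects.

## The problem

Cervical accelerometry records the vibrations of the hyolaryngeal structures
during swallowing with a dual-axis accelerometer placed just below the
thyroid cartilage — anterior-posterior (A-P) and superior-inferior (S-I)
axes. It is studied as a non-invasive complement to videofluoroscopy for
dysphagia screening. Because swallowing physiology is modulated by what is
being swallowed, signal features may differ systematically across liquid
*stimuli* (water, a thin barium suspension, nectar-thick and honey-thick
juices, ordered by viscosity) and across drinking *tasks* (discrete sips vs
sequential drinking). Detecting such stimulus effects is the analysis this
package implements end-to-end; since no raw recordings from the original
protocol are public, a calibrated synthetic generator stands in for the data
and makes every stage testable.

## The method

For each swallow, with preprocessed A-P signal *X* = {x₁…x_n} and S-I
signal *Y*:

- **Moments** — mean, unbiased variance, skewness m₃/m₂^{3/2} and
  (non-excess) kurtosis m₄/m₂² of the amplitude distribution, per axis.
- **Entropy rate ρ ∈ [0, 1]** — the signal is standardised, quantized to 10
  levels, and the Shannon entropy SE(L) of its overlapping length-L patterns
  is computed for L = 10…30. The corrected conditional entropy
  CCE(L) = SE(L) − SE(L−1) + perc(L)·SE(1) (perc = fraction of
  once-occurring patterns) is minimised over L and normalised:
  ρ = 1 − min_L CCE(L)/SE(1). 1 = maximally regular.
- **Cross-entropy rate λ ∈ [0, 1]** — the same construction on mixed
  patterns (one current X symbol with the L−1 current-and-past Y symbols,
  and the mirror direction); λ = 1 − min_L UF(L) with UF the minimum of the
  two directional normalised entropies. 1 = perfectly synchronized axes.
- **Lempel-Ziv complexity** — 100-level quantization, exhaustive-history
  parsing into k minimal unique blocks, C = k·log₁₀₀(n)/n.
- **Memory** — smallest autocorrelation lag τ with r(τ) ≤ 1/e, in seconds.
- **Duration** — (n−1)/f_s, and the zero-lag cross-correlation R_XY(0).
- **Wavelet features** — 10-level discrete Meyer decomposition
  [a₁₀ d₁₀ … d₁]; relative band energies (percent of total), of which the
  five lowest bands are kept for A-P and six for S-I, plus the wavelet
  entropy −Σ p_k ln p_k over all 11 bands, per axis.

That yields 30 features per swallow. The statistical stage collapses
swallows to one median per participant × stimulus cell, runs a
participant-blocked Friedman test per feature and task (α = 0.05), and for
significant features runs the six pairwise Wilcoxon rank-sum tests with
Bonferroni correction (familywise α = 0.05).

Preprocessing mirrors the acquisition chain: recordings are segmented by an
envelope-based fuzzy c-means detector (or externally supplied boundaries),
filtered through axis-specific inverse FIR filters [1, −a₁, …, −a_P] built
from modified-covariance AR fits of noise-only baseline recordings, and
denoised by soft-thresholding all detail bands at
T = (median|d₁|/0.6745)·√(2 ln n).

## Worked example

`examples/05_stimulus_effects.py` simulates the full 17-participant
protocol (17 sequences each, four swallows per sequence) and runs the
statistical stage on five features:

```
discrete task — significant: ['duration', 'entropy_rate_ap', 'entropy_rate_si', 'lz_ap', 'lz_si']
          duration  p=8.34e-10    2.0592   2.0325   2.1904   2.2786
   entropy_rate_ap  p=8.51e-11    0.0096   0.0296   0.1069   0.2038
             lz_ap  p=4.48e-10    0.7053   0.6943   0.6872   0.6726
  ...
  post-hoc entropy_rate_ap: water vs honey, adjusted p = 0.0000
```

The four columns are the per-stimulus means (water, barium, nectar, honey):
swallow duration and entropy rate rise with viscosity while Lempel-Ziv
complexity falls — thicker boluses produce slower, more regular, more
predictable signals — and the blocked Friedman tests detect these effects
decisively at n = 17. The other examples demonstrate session simulation,
segmentation against ground truth, single-swallow features and the wavelet
energy distribution.

A thin CLI wraps the same stages:

```bash
swallowflow run-all --out run1 --seed 7 --participants 3 --sampling-rate 500
```

writing recordings, `features.csv`, per-task JSON reports, Markdown summary
tables and a manifest with the SHA-256 of every output.

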