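# Methods

## Signal model and decomposition

Both pipelines treat EEG as a piecewise-stationary signal whose
discriminative content lies below ~40 Hz. Each analysis window is decomposed
by a 4-level discrete wavelet transform with the Daubechies-2 wavelet: a
two-channel filter bank whose low-pass h[·] and quadrature-mirror high-pass
g[k] = (−1)^k h[L−1−k] are applied recursively to the running approximation,
each followed by dyadic downsampling. The db2 filter taps are hard-coded to
16 significant digits from the standard tabulation, not re-derived at
runtime, so coefficients are bit-reproducible across platforms. D1 and D2
are computed and retained in the `SubbandSet` even though the feature set
uses only D3, D4 and A4; subband selection happens downstream.

**Boundary handling.** The originating analysis did not state an extension
mode, so it is declared rather than inferred: the default is half-point
symmetric extension (the de-facto default of the mainstream wavelet
toolboxes), with `periodization` and `zero` available via configuration.
Coefficient lengths follow the usual conventions — ⌊(n + L − 1)/2⌋ per level
for symmetric/zero, ⌈n/2⌉ for periodization (odd lengths padded by repeating
the final sample). Periodization is the orthogonal case: it conserves energy
to ~1e−12 relative and inverts exactly, which the test suite uses as a
transform-correctness oracle alongside coefficient-level agreement with
PyWavelets. Because the extension mode of the original feature tables is
unknown, exact reproduction of those tables is not asserted anywhere.

## Features

Per retained subband (D3, D4, A4): maximum, minimum, mean, sample standard
deviation (N−1 denominator, exactly as the defining formula is written), the
energy Σ|c_j|², and the energy-weighted entropy Σ c_j² log(c_j²). Choices
made where the definitions are underspecified:

* **Entropy log base**: natural log, declared (the defining formula writes
  `log` without a base); 0·log 0 = 0 handles zero coefficients. The quantity
  is not normalised to a probability distribution, so it scales with energy
  and can be negative for sub-unit coefficients.
* The entropy and standard-deviation formulas are written for detail
  coefficients but are applied unchanged to A4 as well — required for the
  18-value vector (6 statistics × 3 subbands) to exist.
* **IQR quartiles**: linear interpolation of order statistics at p = 0.25 /
  0.75 (the default of mainstream numeric environments); only Q3 − Q1 is
  defined upstream.
* A single-coefficient subband reports standard deviation 0 with a warning
  instead of failing; empty inputs are errors.

The feature order is frozen — `[max, min, mean, std, entropy, energy]` ×
`[D3, D4, A4]`, then `[IQR, MAD]` — so serialized models are portable. The
order within the set was an open choice; it is documented, not meaningful.

## Classifier

"Linear classifier" is implemented as classical pooled-covariance linear
discriminant analysis: w_k = Σ⁻¹μ_k, b_k = −½μ_kᵀΣ⁻¹μ_k + ln π_k with
empirical priors and an N − K pooled-scatter denominator; prediction is the
score argmax with a deterministic lowest-class-index tie-break. This is the
textbook reading of a trained linear decision rule of the era; a
least-squares-to-indicator trainer (`trainer="lsq"`) is available since both
are linear in the same sense. If the pooled-covariance solve is singular or
numerically unreliable (relative residual above 1e−6), the solver falls back
to a ridge-regularised system (Σ + ε·tr(Σ)/d·I, ε = 1e−8) with a warning.
No feature standardisation is applied by default; optional z-scoring stores
train-set statistics in the model. Models serialize to JSON and predict
purely from stored weights.

## Event pipeline

4096-sample channels are cut into 16 non-overlapping 256-sample rectangular
frames. The 10/6 train/test split is positional (frames 1–10 train, 11–16
test) — the original protocol gives counts, not identities, so a
deterministic rule is declared. Features from all channels of all three
classes are pooled into one training matrix, matching the single reported
classifier. Class coding: 0 = normal, 1 = ictal, 2 = interictal.

**Reference confusion matrix.** The published-style reference matrix used by
tests and `scripts/acceptance.py` has an internally inconsistent ictal row:
it sums to 510 while the other rows sum to 600, yet the accompanying 91 %
ictal sensitivity and 84.2 % overall accuracy are consistent with a 600-frame
row. The ictal diagonal is therefore treated as a typographical issue and
reconstructed as 600 − 9 − 45 = 546 when a consistent matrix is requested
(`reference_confusion(consistent=True)`); the printed counts remain available
unchanged. The reference specificity is printed truncated (514/600 = 85.67 %
→ 85.6 %), and the acceptance script reproduces that truncation.

## Onset pipeline

Records are segmented into 1-second epochs (epoch k covers [k, k+1) s;
annotation times are 0-based seconds, half-open intervals). Every channel of
every epoch yields the 20-feature vector; one pooled binary model scores all
channels. The 23×20 stacking of the original description is ambiguous
between per-channel and concatenated-channel vectors; the per-channel
reading is chosen because the voting rule consumes per-channel outputs. An
epoch is declared ictal when the fraction of positive channel votes is
**≥ 0.6** (the boundary comparison is declared as ≥; 14 of 23 channels
declares, 13 does not).

* **Seizure split**: chronologically first ⌈0.6·n⌉ seizures train, the rest
  test (16 → 10/6, 3 → 2/1). The historical per-patient table this mirrors
  is not perfectly uniform (one 11-seizure patient used 8/3, and one
  7-seizure patient used 4/3, below 60 %); explicit counts can be passed via
  `OnsetConfig(n_train_seizures=...)` for such cases. The irregularity is
  noted here rather than silently corrected.
* **Normal training epochs**: for each training-seizure epoch, one normal
  epoch is sampled (seeded) from records containing no test seizure, at
  least 60 s away from any seizure in its record. How many and which normal
  epochs the original analysis used is unstated; matching the positive count
  keeps the classes balanced.
* **Latency**: the detected onset is the start of the first declared epoch
  whose start time is at or after the annotated onset, searched up to the
  annotated seizure end, so latency is never negative; declarations before
  the onset count toward false detections instead.
* **False-detection percentage**: 100 × declared non-seizure epochs /
  non-seizure epochs evaluated, over all epochs of the test records lying
  outside annotated seizures. No guard band is excluded from this
  denominator.

## Synthetic generator

The generator emulates the two record families at their native formats and
rates: single-channel 4096-sample integer-valued segments at 173.61 Hz, and
23-channel 256 Hz multichannel records with annotation sidecars. Regimes
(amplitudes chosen once, microvolt-scale):

| regime | construction | scale |
| --- | --- | --- |
| normal | 0.53–40 Hz band-limited Gaussian noise | σ ≈ 50 |
| interictal | delta-dominant (0.53–4 Hz) background ≈ 2.4× baseline + ~1 Hz Poisson biphasic spikes at ≈ 8× baseline | spikes ≈ 400 peak |
| ictal | 3 Hz spike-wave (slow wave + one sharp transient per cycle, slow amplitude modulation) ≥ 10× baseline + noise | ≈ 550–700 peak |

The ictal/normal contrast mirrors the order-of-magnitude gap between
reported interictal-free and ictal subband statistics (A4 σ of order 10² vs
10³) without attempting exact table reproduction. In CHB-like records the
ictal pattern is added on a seeded 80 % subset of channels (≥ 70 % required)
inside each annotated interval, so the 60 % vote can fire. Synthetic
patients consist of one 60 s record per seizure (seizure at 20–35 s) plus
enough seizure-free 60 s records to supply matched normal epochs.

**What this does and does not show.** The synthetic regimes are separated by
design — large amplitude and spectral contrasts, stationary backgrounds, no
artifacts (EMG/EOG), no electrode noise, no patient-to-patient variability,
and identical seizure morphology on most channels. Passing the end-to-end
tests therefore certifies that the chain (decomposition → features →
classifier → voting → latency scoring) is implemented correctly and is
deterministic, not that it attains any particular accuracy on real archives;
real-data performance is covered only by the optional integration tests that
run when local copies of the archives are present.

## Problem sizes and determinism

Default experiment sizes are modest by choice — 12–20 synthetic channels per
Bonn-like set and five 5-seizure synthetic patients — since the easy-regime
contrasts saturate quickly and larger sizes add nothing but runtime. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`
with derived seed sequences); identical seed and configuration reproduce
reports bit-for-bit, which the suite asserts.

## Known limitations

* The EDF writer is deliberately minimal (16-bit, one integer sampling rate,
  no embedded annotations); it exists so synthetic records can round-trip
  through the same established reader used for real files.
* Mixed-rate EDF files are refused rather than resampled.
* LDA assumes shared within-class covariance; with strongly heteroscedastic
  classes the least-squares trainer may behave differently, and neither is a
  modern classifier — the linear rule is the point, not the ceiling.
* Latency resolution equals the epoch length (1 s); sub-epoch onsets are
  rounded up to the next epoch boundary.
* The event experiment's positional frame split means temporal leakage
  within a channel is possible in principle (adjacent frames share slow
  trends); the original protocol is followed as declared.
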