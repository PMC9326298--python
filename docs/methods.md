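# Methods

This note documents the models, conventions and design choices behind
the package, in the order the analysis runs.

## Signal model and acquisition conventions

Recordings are mono accelerometer signals sampled at 44 100 Hz and
24-bit resolution, stored as dimensionless amplitudes in [−1, 1]
(integer PCM divided by 2^(bit depth − 1); this fixed normalization
makes the dB-full-scale reference well defined).  The manifest CSV
carries the experimental factors per recording: species, source–sensor
distance *z* (cm), tissue (bark or phloem), tissue width *w* (cm), and
log/subject identifiers.  Acquisition gain is analog and has no digital
counterpart, so it is not modelled.

## Spectral analysis

All time–frequency analysis uses a 1024-bin FFT with a symmetric
flat-top window of 1024 samples and 3/4 overlap (hop 256 samples
≈ 5.8 ms; frequency resolution ≈ 43 Hz).  The flat-top window is the
amplitude-accuracy choice for narrowband level measurement; its large
equivalent-noise bandwidth is absorbed by scipy's density scaling, so
the Welch PSD integrates to the mean squared amplitude (Parseval,
verified to 5% on white noise).  Welch estimation reuses the same
window/overlap settings for consistency; a signal shorter than one
segment is zero-padded to a single segment with a warning.

Power is reported in dB full scale (dBFS): 10·log10(P/P_max), where
P_max is the maximum power value across the analysed collection, so the
loudest observed cell is 0 dBFS and everything else is negative.  The
scope of the reference collection is a parameter (`reference=` in
`to_dbfs` and `band_power_decay`), defaulting to the collection being
converted; the pipeline pins one global reference across all
spectrograms and PSDs of a run.  Linear power is clamped at 10⁻¹² of
the reference before taking logs, so silence maps to −120 dBFS rather
than −∞.

Band-decay tables average in **linear** power — across recordings at a
distance, then across the bins of each 2 kHz band — and convert to dB
last.  Averaging dB values would under-weight the loud recordings that
dominate the physical energy.

## Segmentation

The energy envelope is the per-frame mean of the linear-power
spectrogram; its arithmetic mean is the detection threshold.  Frames
strictly above threshold are active (strictness makes the constant
envelope yield zero detections); active runs separated by at most
`max_gap_frames` (default 2) are merged, and runs shorter than
`min_len_frames` (default 3 ≈ 17 ms) are dropped.  Both defaults sit
well below the chirp durations of the study species (~40–60 ms) and are
exposed as configuration, since no minimum-duration or gap rule is
inherent to the threshold idea.  The envelope is computed on linear
power: a mean threshold on dB values is dominated by the noise floor.
Because the threshold scales with the envelope, segmentation is exactly
invariant to global amplitude scaling.

## Features

Each call's "mean spectrum" is the mean over its frames of the linear
spectrogram columns.  From it:

- **centroid frequency** — power-weighted mean frequency (weights are
  linear power; the centre-of-mass analogy needs non-negative weights);
- **dominant frequency** — the maximal bin, ties broken toward the
  lowest frequency (a documented convention; ties are measure-zero on
  real data);
- **−3 dB bandwidth** — the span between the *outermost* crossings of
  half the peak power, linearly interpolated between bins.  Outermost
  crossings are robust to ripple inside the passband.  Degenerate
  spectra are flagged: single-bin peaks report one bin width, spectra
  that never drop 3 dB report the full axis span;
- **duration** — frames × hop / sample rate;
- **mean amplitude** — mean linear power of the mean spectrum in dBFS
  against the run's global reference.  (Whether the amplitude feature
  is referenced globally or per recording does not affect downstream
  results, because features are min–max normalized before use.)

Min–max normalization to [0, 1] is fitted per analysis subset — the
pooled two-species table at one distance — because identification is
evaluated per distance.  The (min, max) pairs are stored for exact
inversion; a constant column is mapped to 0.5 and flagged.

## Attenuation model

Received power is modelled as P(z) = ψ·e^(−αz) − c, with ψ (dB) the
decaying component's scale, α (cm⁻¹) the attenuation coefficient and c
(dB) the asymptotic noise floor.  Fitting is nonlinear least squares on
the averaged power level at each distance:

- initialization c₀ = −min(P), α₀ from a log-linear fit of
  log(P + c₀ + ε) against z, ψ₀ from the closest observation;
- up to 5 restarts with jittered α₀ (exponential fits are sensitive to
  initialization); best converged solution by SSE wins;
- bounds ψ ≥ 0, α ≥ 0 (physical decay toward a floor);
- 95% CIs from the Jacobian-based linearized covariance with a
  t-quantile at n − 3 degrees of freedom.

Noiseless data generated from any (ψ > 0, α ≥ 0, c) on the nine study
distances is recovered to ~1e-13 (tested across all published parameter
sets).  With 0.2 dB Gaussian noise the median relative error of α stays
below 10% across the published α range when ψ is of typical size
(~8–19 dB); identifiability degrades when ψ shrinks toward the noise
scale, since the whole curve then spans only a few dB.

Two conventions are reported verbatim rather than silently corrected:
the noise relation N = 10^(−c) (for c ≈ 25 dB the usual decibel
convention 10^(−c/10) is far more plausible; both fields are exposed on
the model object), and α's units, recorded as cm⁻¹ as the exponent
P(z) requires even where attenuation coefficients are colloquially
quoted in dB·cm⁻¹.

The width model α = slope·w + intercept is ordinary least squares per
tissue on (w, α) pairs.  The package embeds the published
per-condition decay parameters (`EMPIRICAL_DECAY_MODELS`) both as the
width-regression input and as generating truth for synthetic decay
series.  Note that OLS on the *printed, 3-decimal-rounded* bark pairs
yields slope −0.1902 / intercept 0.2738, whereas the published bark
line is −0.191/0.275 — consistent with that line having been fitted on
unrounded coefficients; the phloem line (−2.030/0.724) reproduces
exactly.

## Identification

Features (normalized, per distance) feed two families:

- **unsupervised**: k-means (squared Euclidean), fuzzy c-means
  (fuzzifier m = 2, defuzzified by maximal membership; implemented
  in-package as standard alternating optimization since no installed
  library provides it), Gaussian mixtures (EM), and DBSCAN (ε = 0.25,
  50 minimum points — scaled to min(50, max(5, n/10)) for tables under
  500 rows, since the published value presumes a several-hundred-call
  dataset).  Cluster labels are scored against species by the
  accuracy-maximizing assignment over the two permutations; DBSCAN
  noise points always count as errors, and more than two clusters fall
  back to the best cluster-to-two-class map (flagged).
- **supervised**, with stratified fivefold cross-validation: decision
  tree (Gini, 4 splits), LDA and QDA (full covariance), unregularized
  logistic regression, naive Bayes with a per-feature Gaussian kernel
  density (implemented in-package; the scikit-learn version is
  Gaussian-parametric), SVMs (linear, quadratic, cubic, RBF), KNN with
  Euclidean, cosine and Minkowski (p = 3, the conventional "cubic"
  exponent) metrics at 10 neighbours with equal weights, a bagged tree
  (30 learners, 712 splits) and random-subspace LDA and KNN ensembles
  (30 learners, 3 subspace dimensions).

One seed governs fold assignment, clustering initialization and
ensemble resampling, making the whole battery deterministic.  The
reported score per (algorithm, distance) cell is mean fold accuracy
(supervised) or aligned-cluster accuracy (unsupervised), in percent.
t-SNE (perplexity min(30, (n−1)/3), PCA initialization) is provided
for visualizing cluster separation only and never enters scoring.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
not a physical wood-acoustics simulation (no dispersion, modes or
reflections):

- **chirps** are band-limited Gaussian-noise bursts: white noise shaped
  in the frequency domain by a Gaussian amplitude profile (half-power
  half-width = the species' band half-width) and bounded in time by a
  Tukey taper (5% per edge).  The tapered-cosine envelope was chosen
  over a Gaussian envelope because it gives the burst a well-defined
  finite support, which is what frame-accurate ground-truth boundaries
  are defined against; ground-truth frames are those whose analysis
  window centre falls inside the burst support.
- **species presets** (configuration, not claims about the real
  animals): chirp durations 60 vs 40 ms, intervals 0.25 vs 0.30 s, band
  centres 5.0 vs 5.5 kHz, half-widths 1.5 vs 1.2 kHz, source levels 0
  vs −6 dB — separable at close range, merging far out.
- **propagation** scales each burst by P(z) − P(0) from a generating
  (ψ, α, c) triplet and adds a stationary Gaussian floor at −c dB.
  Bandwidth compression is modelled as an extra
  `alpha_slope_per_khz_cm`·z dB of attenuation per kHz of offset from
  the band centre, applied on top of the band shape and normalized so
  it strictly removes energy; the default 0.035 dB/(kHz·cm) shrinks
  the measured −3 dB bandwidth by roughly 40% between 5 and 60 cm.
- the **feature benchmark** bypasses audio entirely: per distance, two
  unit-variance 5-D Gaussian clouds whose means differ by d(z)/√5 per
  feature with alternating sign, giving Euclidean separation d(z) and
  Bayes error Φ(−d/2).  The alternating sign matters: a same-sign
  shift would place both class means along the all-ones diagonal, a
  degenerate geometry that direction-only metrics (cosine KNN) cannot
  separate and that real acoustic features (centroid down, bandwidth
  down, amplitude down, duration differing) do not exhibit.  The
  default schedule maps distances {5, 10, 15, 20, 30, 40, 60} cm to
  separations {10, 8, 6, 5, 2.2, 1.7, 0}, reproducing the qualitative
  identification envelope: ≥97% everywhere at close range, ~75–88% at
  intermediate distances, chance at the merged setting.

Everything regenerates bit-identically from (configuration, seed);
per-recording seeds derive deterministically from the master seed.
What passing tests on this generator show about real data is limited
accordingly: they validate the measurement chain (segmentation,
features, fitting, scoring) under the assumed signal structure, not
robustness to field noise, overlapping singers, or wood-specific
propagation effects.

## Problem sizes and numerical choices

The default test and benchmark sizes are chosen as realistic study
conditions: nine distances (5–100 cm), 500 calls per species per
distance in the feature benchmark (large enough that DBSCAN's published
minimum-points value applies unscaled), 200 Monte-Carlo replicates for
noise-recovery statistics, 50 seeds for segmentation fidelity.
Tie-breaks, floors and degenerate-input behaviour are documented at the
function level: lowest-frequency tie-break for dominant frequency,
0.5-fill for constant feature columns, −120 dBFS log floor, strict
inequality in the segmenter, and flagged degenerate bandwidths.

## Known limitations

- The segmenter assumes one singer per recording; overlapping calls
  merge into single detections.
- The mean-envelope threshold presumes the within-recording duty cycle
  of calls is moderate; recordings that are almost all signal (or pure
  noise) shift the threshold toward the signal level.
- α estimated from the exponential fit is a bulk coefficient per
  condition; frequency-resolved attenuation is only available
  qualitatively through the 2 kHz band tables.
- The identification battery's absolute accuracies on synthetic
  benchmarks characterize the algorithms under the generator's
  assumptions, not field performance on the real species.
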