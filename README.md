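# woodstrid

Analysis of stridulatory sounds propagating inside wood, built around the
model system of two phloem-dwelling bark beetles (*Hylurgus ligniperda*
and *Hylastes ater*, Scolytinae) recorded through *Pinus radiata* bark and
phloem at source–sensor distances of 5–100 cm.

Bark- and wood-boring beetles communicate with single-note, quasiperiodic
stridulations whose energy concentrates around 3–7 kHz.  Because the
substrate attenuates this signal strongly and frequency-dependently, how
far a call carries — and how far away the *species* can still be told
apart — are quantitative questions.  This package provides the complete
measurement chain to answer them, plus a ground-truthed synthetic
generator so every stage is testable without field recordings:

- **audio I/O** — mono 24-bit PCM WAV (44.1 kHz) and a CSV recording
  manifest (species, distance, tissue, tissue width, log/subject IDs);
- **spectral analysis** — spectrograms and Welch power spectral
  densities (1024-point FFT, symmetric flat-top window, 3/4 overlap),
  dB-full-scale scaling against the collection maximum, and per-2 kHz-band
  power-decay tables over distance;
- **segmentation** — calls detected as maximal runs of spectrogram
  frames whose mean energy exceeds the recording's mean-envelope
  threshold;
- **features** — five descriptors per call: centroid frequency
  *f*<sub>c</sub> = Σ*f*<sub>i</sub>*u*<sub>i</sub>/Σ*u*<sub>i</sub>,
  dominant frequency, −3 dB bandwidth, duration, and mean amplitude
  (dBFS), min–max normalized to [0, 1];
- **attenuation** — received power modelled as
  *P*(*z*) = *ψ*e<sup>−*αz*</sup> − *c* (z in cm, *α* in cm⁻¹), fitted
  by nonlinear least squares with RMSE and 95% CIs, plus the linear
  regression of *α* on tissue width *w*;
- **identification** — distance-stratified species discrimination with
  four clustering methods (k-means, fuzzy c-means, Gaussian mixtures,
  DBSCAN) and fifteen cross-validated classifiers (trees, discriminant
  analyses, logistic regression, kernel naive Bayes, four SVM kernels,
  three KNN metrics, bagged and random-subspace ensembles), scored as
  accuracy (*T*p + *T*n)/(*T*p + *T*n + *F*p + *F*n), with an optional
  t-SNE ordination for visualization.

## Worked example

Fit the decay model to noisy synthetic observations at the nine study
distances and regress attenuation on tissue width
(`examples/03_attenuation_fit.py`):

```text
generating: psi=18.604  alpha=0.211  c=24.998
fitted:     psi=23.272  alpha=0.242  c=25.099  (rmse 0.179 dB)
alpha 95% CI: [0.191, 0.293]
predicted power at 5 cm: -18.15 dBFS
bark: alpha = -0.190 * w + 0.274  (per-cm attenuation vs tissue width)
phloem: alpha = -2.030 * w + 0.724  (per-cm attenuation vs tissue width)
```

The fitted curve recovers the generating attenuation coefficient within
its noise-driven confidence interval (0.211 ∈ [0.191, 0.293]); the
width lines are ordinary least squares on the published per-condition
coefficients, with the steeper phloem slope showing how strongly the
moist inner tissue's width moderates attenuation.

Distance-stratified identification on the default benchmark
(`examples/04_species_identification.py`):

```text
                5.0    10.0  15.0  20.0  30.0  40.0  60.0
kmeans         100.0  100.0  99.7  99.0  87.4  80.6  52.0
gmm            100.0  100.0  99.8  99.0  87.8  79.9  52.0
lda            100.0  100.0  99.7  99.1  87.2  80.4  47.0
svm_rbf        100.0  100.0  99.7  99.1  86.4  78.7  49.7
knn_euclidean  100.0  100.0  99.9  98.8  84.9  76.9  50.2
```

Accuracy (%) is near-perfect while the species' feature distributions
remain separated (short distances), declines through intermediate
distances as attenuation strips the discriminating spectral content,
and reaches the ~50% chance level once the distributions merge.

The other examples cover synthesis + segmentation (`01`), band-wise
power decay (`02`) and the end-to-end file pipeline (`05`).  A thin CLI
wraps the same stages:

```bash
woodstrid generate --out data --seed 5
woodstrid run-all --manifest data/manifest.csv --out run --seed 0
woodstrid report --attenuation-json run/attenuation.json
```

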