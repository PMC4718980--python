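# Methods

## The modulation spectrum

A sustained vowel is, to first order, a harmonic carrier whose subband
amplitudes fluctuate slowly.  The modulation spectrum (MS) makes those
fluctuations explicit: it is a complex matrix `E(f_a, f_m)` indexed by
acoustic frequency `f_a` (which carrier subband) and modulation frequency
`f_m` (how fast that subband's envelope fluctuates).  A steady tone is a
single point on the `f_m = 0` column; sinusoidal amplitude modulation at
rate `r` adds sidebands at `f_m = ±r` in the carrier's acoustic band.
Dysphonic phonation — jitter, shimmer, tremor, breathiness — disperses
energy from the 0 Hz column into modulation sidebands, and the six scalar
metrics below quantify that dispersion.

### Computation

Incoherent (Hilbert-envelope) demodulation over an sTFT filterbank:

1. **Filterbank.** A Hann-windowed sTFT with window length
   `2·(n_acoustic_bands − 1)` samples (254 for the default 128 bands), so the
   one-sided FFT has exactly `n_acoustic_bands` uniform bands with centers
   `k·fs/254` spanning 0..fs/2 (≈98.4 Hz apart at 25 kHz).  Hop
   `stft_hop_samples = 32`, giving an envelope sampling rate of
   `fs/32 = 781.25 Hz` — a usable modulation range of ±390 Hz, comfortably
   above the 220 Hz upper limit any tuning grid uses.
2. **Envelope.** The magnitude of each band's coefficient sequence over
   time.  For a narrowband subband this equals the Hilbert envelope of the
   subband signal; it is the standard incoherent detector.
3. **Modulation FFT.** Each envelope (133 samples for a 180 ms frame) is
   zero-padded to `n_mod_bands = 1024` points, transformed, and the columns
   reordered to a symmetric −/0/+ axis with bin spacing
   `781.25/1024 ≈ 0.763 Hz`.  1024 counts two-sided bins, matching displays
   that show negative modulation frequencies.  With an even FFT length the
   lone −Nyquist bin (−390.6 Hz) has no positive partner; every other column
   pair satisfies `|E(f_a, f_m)| = |E(f_a, −f_m)|` for real input.

**DC handling.** The envelope of a voiced frame has a large mean, and a
133-point rectangular window zero-padded to 1024 bins leaks that mean into
the neighbouring modulation bins — enough to bury a genuine 50 Hz sideband
under the DC skirt.  We therefore remove the envelope mean before the
modulation FFT and re-assign its total (the value an unpadded transform
would place at DC) to the 0 Hz bin.  The 0 Hz column still carries the
central-band energy, the AM-tone phenomenology is preserved (central point
remains, at a higher level than the ±rate sidebands), and low-rate sidebands
are measurable.  No taper is applied to the residual envelope; the ±0.76 Hz
bin spacing and the ≈5.9 Hz intrinsic resolution of a 170 ms envelope locate
a 50 Hz AM peak to well under 1 Hz.

## The six metrics

All metrics are computed per 180 ms frame on the restricted MS (see tuned
ranges below); RALA on the linear modulus, everything else on
`20·log10|E|` with a −120 dB floor for zero cells.

- **MSH** (homogeneity): `Σ |E_dB(a,m) − mean_{N×N}(a,m)|`, the summed
  absolute deviation of each cell from its N×N neighbourhood mean.  Printed
  formulations of this statistic sometimes omit the absolute value, but
  without it the double sum telescopes toward zero for any matrix; the
  magnitude form is the meaningful (and standard image-homogeneity) reading.
  For even N the window cannot be centred: it spans rows/columns
  `[i − N/2 + 1, i + N/2]`, displacing the anchor from the window mean —
  which is exactly why even masks discriminate better (the mean is less
  correlated with the anchor cell).  Border windows are truncated to
  in-matrix cells.  Implementation is an integral image (O(1) per cell); the
  matrix is mean-centred first so a constant matrix yields exactly 0.
- **CIL**: the intersection of the increasing and decreasing cumulative
  histogram curves of the dB modulus, which is the median; implemented via
  the same percentile routine as MSP so `CIL == MSP50` holds bit for bit.
- **RALA**: `N_A / N_B`, cells at-or-above vs. below the linear-mean
  modulus.  More dispersion away from the 0 Hz column ⇒ more cells above the
  mean ⇒ larger RALA.
- **MSP25/75/95**: percentiles of the dB modulus (linear interpolation
  between closest ranks — the numpy convention, shared by the test oracles).
  MSH is computed on the dB modulus; levels language and the image-homogeneity
  framing both point that way, and it is recorded as a configuration choice.

## Detection and evaluation

Each metric is evaluated alone with an EER-threshold detector under
speaker-grouped 7-fold cross-validation: all frames of a speaker share a
fold, folds are stratified by class (round-robin over per-class shuffles with
a global position counter, so small corpora still fill every fold).  On the
training folds the detector learns the orientation (does the pathological
class score high or low? — decided by class means) and the threshold
minimising |FPR − FNR| over all midpoints of adjacent sorted unique scores
plus ±∞; ties break toward the lower threshold, scores exactly at the
threshold classify as pathological (favouring sensitivity).  EER is
(FPR+FNR)/2 at that point.  Efficiency is the fraction of held-out items
classified correctly; frame-level decisions are the default, recording-level
(mean frame score per recording) is available.

## Staged tuning

Four coordinate-wise stages, each freezing its winner before the next:
frame length (20–200 ms, 20 ms steps), MSH mask size (2–12, MSH only),
modulation upper limit (20–220 Hz, 20 Hz steps), acoustic margins (lower
0–1000 Hz in 100 Hz steps × an upper set
{1200, 1500, 1800, 2000, 2500, 3000, 4000, 5000, 6000, 8000, 9000, 12000} Hz).
Within a tolerance band (default 1 efficiency point) of the maximum the
preferred extreme wins — the shortest frame, since shorter frames better
satisfy the stationarity assumption.  When tuning on two corpora the
consensus value maximises the worse of the two min-max-normalized efficiency
curves: a reproducible rule standing in for the judgment of picking ranges
that behave well in both corpora rather than a single-corpus spike.  A
carry-set of modulation limits {20, 80, 120, 140, 200} Hz is available for
fanning stage 3's shortlist into stage 4.

The shipped `tuned_defaults()` — 180 ms frames, 6×6 mask, and per-metric
(modulation upper, acoustic range) of MSH (80 Hz, 200–9000 Hz),
CIL (80, 0–2000), RALA (200, 800–6000), MSP25 (80, 0–1800),
MSP75 (200, 0–2000), MSP95 (200, 0–9000) — is the configuration selected by
this procedure on clinical tuning corpora and is emitted exactly.

## GMM ensemble and association statistics

The ensemble fits one diagonal-covariance Gaussian mixture per class
(k-means initialisation, variance floor 1e−6, fixed seed) on z-scored
six-metric vectors, standardisation learned on the training folds only, and
decides by larger class log-likelihood.  CV is speaker-grouped as above;
per mixture size we report mean fold efficiency and a 95%
normal-approximation binomial half-width `1.96·√(p(1−p)/n)` on the pooled
decision count.

Metric association is summarised by the Pearson correlation matrix (with
two-sided p-values) and a relative mutual information matrix: plug-in
histogram MI with equal-width bins over each metric's observed range
(default 32 bins), normalized by `log2(n_bins)`.  Under this normalization
the diagonal is the normalized marginal entropy — below 1 for peaked
distributions — which reproduces the qualitative behaviour of such tables;
the normalization is a documented estimator choice, not a canonical
definition.

## Synthetic corpora

No public corpus of labeled sustained vowels is bundled, so the generator
synthesises one: each synthetic speaker phonates `n` harmonics with 1/k
roll-off whose fundamental phase is accumulated cycle by cycle.  Per cycle,
the period is perturbed by Gaussian jitter (SD = jitter_pct, clipped at
±3 SD) and the amplitude by Gaussian shimmer; a slow sinusoid adds tremor;
white noise is scaled to a target harmonics-to-noise ratio (power ratio of
the harmonic to the noise part, before peak normalization).  This is an
additive source model, not a glottal-flow model: the metrics probe
modulation structure, which perturbation of period/amplitude/noise creates
directly, so spectral-tilt and formant realism are deliberately out of
scope.  Consequently, passing tests demonstrate that the machinery recovers
planted perturbation structure — not clinical performance on real voices.

Class parameter ranges (uniform draws per speaker):

| parameter | normal | pathological (strong) | pathological (moderate) |
|---|---|---|---|
| f0 (Hz) | 100–220 | 100–220 | 100–220 |
| jitter (%) | 0–0.3 | 1.5–4 | 0.5–1.5 |
| shimmer (%) | 0.5–2 | 4–10 | 2–5 |
| HNR (dB) | 25–35 | 5–15 | 15–25 |
| tremor rate (Hz) | 3–7 | 3–7 | 3–7 |
| tremor extent (%) | 0–1 | 2–8 | 1–3 |

Jitter/HNR ranges follow the conventional normative vs. dysphonic bounds;
shimmer and tremor ranges, for which no single convention exists, were fixed
once at values inside the normative (normal) and clearly perturbed
(pathological) regions of the acoustic-analysis literature.  `effect="null"`
draws both classes from the normal ranges, so labels carry no signal.  The
corpus seed fixes every draw bit-for-bit.

## Problem sizes and numerical choices

- Planted-effect and ensemble checks use 10 speakers per class × 3 s
  (16 frames each, 320 frames per corpus), the geometry the package's
  synthetic study conditions specify; null calibration repeats it over 20
  seeds.  The class-separation property test uses 5 speakers/class × 1.08 s
  over 20 seeds — a smaller geometry chosen to keep that auxiliary check
  cheap while still averaging over corpora.
- GMM component grids in tests use {4, 8, 16, 32}; 64 components would
  exceed the per-class training rows of a 320-frame corpus.
- dB floor −120 dB; GMM variance floor 1e−6; EER tie-break toward the lower
  threshold; threshold ties classify as pathological.
- Resampling is rational polyphase (Kaiser-windowed sinc); the rate ratio is
  approximated with denominator ≤ 1000 (exact for common rates).
- Percentile convention: linear interpolation between closest ranks,
  everywhere (CIL, MSP, oracles).

## Known limitations

- The synthetic source model omits formants, vowel identity, and
  pathology-specific mechanisms (polyps, paralysis, ...); results on it
  validate the pipeline, not clinical accuracy.
- Whether MSH should run on linear or dB modulus is ambiguous; dB is the
  default and a config switch documents the choice.
- The relative-MI normalization is an estimator reconstruction (see above).
- "Efficiency" granularity at recording level is coarse on small corpora
  (one decision per recording).
- The −Nyquist modulation bin is asymmetric by construction of an even-length
  FFT; band restrictions at the tuning-grid limits (≤ 220 Hz) never include it.
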