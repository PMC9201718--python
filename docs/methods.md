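# Methods

This package implements an EEG depression-screening pipeline around
SparNet, a region-parallel one-dimensional convolutional network with
squeeze-and-excitation (SE) channel attention, together with the
preprocessing it assumes (phase-space-reconstruction denoising, spectral
feature extraction and 3σ feature smoothing) and the paired
leave-one-subject-out (LOSO) evaluation protocol.  This note documents the
model, the numerical choices, the synthetic-data generator and the limits
of what the shipped tests demonstrate.

## Pipeline

For each subject's continuous 128-channel recording (250 Hz, E1…E128
montage, microvolt scale):

1. **Band-pass filter**, 1–40 Hz.  Butterworth, low-pass prototype order 6,
   applied forward–backward (`sosfiltfilt`) so epochs are not phase-shifted.
   With this design the 50 Hz mains component is attenuated to below 6 % of
   its input RMS after the two passes while 10 Hz passes within 1 %.  A
   lower-order design (6th-order band-pass transfer function) leaves ~20 %
   of the 50 Hz line and was rejected because line-noise suppression is the
   filter's stated purpose.
2. **Phase-space-reconstruction denoising**, per channel.  The series is
   delay-embedded at dimension d = 3 (Takens embedding); the lag t is
   chosen per channel at the first local minimum of lagged mutual
   information (equal-width histogram, 12 bins ≈ Sturges' rule for the
   series lengths involved; lags 1–25, i.e. up to 0.1 s; MI estimated on
   the first 30 000 samples for speed).  When no local minimum exists the
   lag where MI first falls below MI(1)/e is used, then the maximum lag.
   Each of the three coordinate series is smoothed pointwise by local
   least squares: a quadratic polynomial is fitted to the 4 samples on
   each side of the target — the target itself is *excluded*, so an
   isolated artifact cannot support its own fit — and the fit is evaluated
   at the target position.  Because the window geometry is fixed, this
   prediction is a fixed linear filter, computed once and applied by
   convolution.  The three aligned estimates of each sample are averaged;
   samples whose window is incomplete (series edges) pass through
   unchanged.  A false-nearest-neighbour dimension estimator is provided
   as a diagnostic but does not override d = 3.
3. **Segmentation** into non-overlapping 2-s windows; the trailing partial
   window, the first and the last complete windows are discarded (start/
   end-of-session interference).  A 300-s recording yields exactly 148
   windows.
4. **Spectral features.**  Each window is transformed by FFT (rectangular
   window, magnitudes scaled by 2/N so a bin-aligned sinusoid of amplitude
   A reads A) and sampled at integer frequencies 1–40 Hz (bin 2i at the
   0.5 Hz resolution of a 500-sample window).  Magnitude, not power, is
   used.  A raw/decimated time-domain representation is available for the
   ablation study (anti-aliased FIR decimation, default factor 5).
5. **3σ feature smoothing**, per subject and per (channel, frequency): with
   mean E(Y) and *population* (1/J) standard deviation σ over the J
   windows, values deviating from E(Y) by strictly more than 3σ are
   replaced by the mean of the nearest unflagged windows before and after
   (one-sided at the boundary).  Statistics are computed once from the
   unmodified data.  A single outlier among J−1 identical values has
   deviation √(J−1)·σ, so it is flagged exactly when J ≥ 11.

## Region maps

Five scalp regions — central, frontal, occipital, parietal, temporal — are
defined as ordered lists of montage labels.  The *initial* variant has 12
channels per region; the *final* variant expands the frontal region to 25
channels (73 in total), reflecting the frontal lobe's dominant
contribution to discrimination.  The published channel tables contain
typographic duplicates (a repeated occipital label; repeated and
cross-region labels in the frontal expansion); the shipped JSON configs
resolve each by the nearest unused montage neighbour and mark every such
entry `"substituted": true`.  The per-region counts (12/12/12/12/12 and
25-frontal/73-total) are enforced as hard validation invariants.
Channels are addressed by montage name throughout, never by index.

## Network

Per region r with C_r channels and 40-point features:

    SE(r=2) → Conv1d(C_r×5, 1 filter, valid, ReLU) → MaxPool(2, stride 2)

giving an 18-point feature per region.  The five branch outputs are
concatenated as a 5-channel map, then:

    SE(r=2) → Conv1d(5×2, 1 filter, ReLU) → MaxPool(2, stride 2)
    → Dense(2) → softmax

The SE block squeezes each channel to its length-mean, passes the C-vector
through a no-bias bottleneck (C → ⌊C/2⌋ → C) with ReLU then sigmoid, and
rescales each channel by its gate.  Conv and dense layers carry biases; SE
layers do not.  One filter per conv keeps the merged map literally
"5 regions × features"; the layer table this follows gives kernel extents
but no filter counts, and this is the minimal consistent reading.  Pooling
uses stride 2 (the layer table; a conflicting stride-1 prose statement is
not followed).  The exact trainable-parameter count is reported per layer:
1 595 for the final map with SE, 399 without (the SE bottlenecks carry
three quarters of the weight budget).  Published totals for this
architecture are not reconcilable with any straightforward layer-by-layer
count and are treated as order-of-magnitude context only.

Everything is implemented in numpy with hand-written analytic backward
passes; a finite-difference check verifies every layer's gradient to
1e-4 relative error.  Weights are initialised uniform fan-in scaled with a
per-layer seed stream derived from the run seed, so training is exactly
reproducible.

**Input standardisation.**  Features are z-scored per (channel, frequency)
with statistics from the training windows, applied identically to
validation and test windows.  Raw FFT magnitudes are strictly positive
with channel-dependent scale; without centring, the single-filter global
convolution saturates on one side of its ReLU at initialisation and the
network cannot leave the ln 2 loss plateau.

## Training and evaluation

Mini-batches of 8, categorical cross-entropy, RMSprop (lr 1e-3, ρ 0.9), at
most 50 epochs.  10 % of training windows, stratified by subject and
class, are held out; training stops when this validation loss fails to
improve for 10 consecutive epochs and the best-validation weights are
restored.  The paired LOSO protocol sorts subjects per class by id and
pairs them rank-wise: each fold tests every 2-s window of one depressed
and one control subject never seen in training (24 folds for the 24+24
clinical design; surplus subjects of an unbalanced cohort stay in
training).  Confusion counts are window-level with depression positive;
accuracy, sensitivity, precision, specificity and F1 (harmonic mean of
precision and sensitivity) are reported per fold and pooled, with ROC
curves from full threshold sweeps and trapezoidal AUC.  Per-fold
randomness is keyed by seed + fold index; reports carry a config hash and
all per-fold seeds.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not
physiological EEG.  Each channel is a sum of

- band-limited oscillations (delta 1–4, theta 4–8, alpha 8–13, beta
  13–30 Hz) synthesised in the Fourier domain with independent random
  amplitude and phase per in-band component, with resting-scale RMS
  amplitudes (8/6/12/4 µV);
- 1/f-shaped background noise (spectral exponent β = 1, 5 µV), white
  noise (2 µV) and a 50 Hz mains sinusoid (2 µV);
- sparse raised-cosine artifact bursts (0.2 s, 10× channel SD) at Poisson
  times (2/min), which give the denoiser realistic transients to remove.

Class structure is injected multiplicatively: depressed subjects' band
amplitudes are scaled per region (e.g. frontal theta × 3), keeping
spectra positive and interpretable.  With all multipliers at 1 the two
classes are generated identically.

**Inter-subject variability is deliberately small** (lognormal band-gain
jitter, σ = 0.02, shared across channels).  Subject-level gains span a
low-dimensional space (one gain per band); if they are large relative to
within-window spectral fluctuation, any random assignment of a small
cohort into two classes is linearly separable in that space by chance, and
leave-one-subject-out accuracy no longer distinguishes a real class effect
from cohort geometry — the no-effect calibration (pooled accuracy at
chance) would fail for *any* classifier.  Keeping the jitter below the
window-to-window noise makes the null experiment meaningful.  The clear
consequence: real cohorts have far larger inter-subject variability, so
passing the synthetic signal/null experiments demonstrates that the
pipeline is correct and leak-free, *not* that comparable accuracy would be
reached on clinical data.

## Problem sizes used by the shipped experiments

The end-to-end validation uses 8 + 8 subjects of 300 s each: a
strong-effect cohort (frontal theta × 3) evaluated on 3 folds, and a
no-effect null cohort evaluated on all 8 folds (the null accuracy estimate
is the noisier quantity and uses all 16 test subjects).  Expected
behaviour: signal accuracy ≳ 0.99, null accuracy within a few points of
0.5.  Unit and property tests use smaller montages (10 channels, 2 per
region) and shorter recordings generated on the fly.

## Known limitations

- The EDF codec handles the plain-EDF subset used here (uniform sampling
  rate, 1-s records, int16); EDF+ annotations are not parsed.
- The denoiser's least-squares window (quadratic, ±4 samples) and the
  recombination of coordinate estimates (plain average) are declared
  choices; the source description fixes neither.
- Time-domain ablation input is decimated by default; with very short
  windows the architecture's pooled lengths shrink accordingly.
- Binary classification only; no multi-class support.
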