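# sparnet-eeg

Screening for major depressive disorder (MDD) from resting-state EEG with
**SparNet**: a region-parallel one-dimensional CNN with
squeeze-and-excitation (SE) channel attention, trained on per-window FFT
amplitude features and evaluated with a paired leave-one-subject-out
protocol.  The package is aimed at researchers who want a complete,
reproducible reference implementation of this pipeline — preprocessing,
feature extraction, network, evaluation — that runs end-to-end on seeded
synthetic cohorts, with EDF as an optional entry point for real
recordings.

## The model

Each subject's 128-channel recording (E1…E128 geodesic montage, 250 Hz) is
band-pass filtered to 1–40 Hz (zero-phase Butterworth), denoised by
phase-space reconstruction — the channel is delay-embedded at dimension
d = 3 with a mutual-information lag t, each coordinate series is smoothed
by local least-squares polynomial prediction, and the aligned estimates are
averaged — and cut into 148 non-overlapping 2-s windows.  Window spectra
y_j^i (FFT magnitude at integer frequencies i = 1…40 Hz, window j) are
cleaned by a 3σ rule: values with |y_j^i − E(Y)^i| > 3σ_i are replaced by
the mean of neighbouring windows.

Channels are grouped into five scalp regions (central, frontal, occipital,
parietal, temporal; 73 channels in the shipped final map, 25 of them
frontal).  Per region, SparNet applies

    SE(r=2) → Conv1d(width 5) → ReLU → MaxPool(2,2)

where the SE block gates each channel k by
s_k = σ(W₂ δ(W₁ z))_k with z_k the channel mean (squeeze), δ = ReLU and
σ the sigmoid.  The five branch outputs are concatenated and passed
through a global SE → Conv1d(5×2) → ReLU → MaxPool(2,2) → Dense(2) →
softmax, trained with cross-entropy, RMSprop, batches of 8, early stopping
on a held-out validation split.  Evaluation pairs one MDD and one control
subject per fold (LOSO); confusion counts are window-level with depression
positive, reported as accuracy, sensitivity TP/(TP+FN), precision
TP/(TP+FP), specificity TN/(TN+FP), F1 (harmonic mean), ROC and AUC.

The network is pure numpy with analytic backward passes (gradient-checked
against finite differences); no deep-learning framework is required.

## Worked example

```python
import sparnet as sp
from sparnet.regions import RegionMap

montage = tuple(f"E{i}" for i in range(1, 11))
regions = {"C": ["E1", "E2"], "F": ["E3", "E4"], "O": ["E5", "E6"],
           "P": ["E7", "E8"], "T": ["E9", "E10"]}

# 4 MDD + 4 control subjects, 300 s each; depressed subjects carry a
# 3x frontal theta amplitude effect
spec = sp.CohortSpec(n_mdd=4, n_control=4, duration_s=300.0, seed=5,
                     channel_names=montage, region_channels=regions,
                     effect={"F": {"theta": 3.0}})
cohort = sp.make_cohort(spec)

report = sp.run_experiment(cohort, RegionMap("custom", regions),
                           denoise=False, n_folds=3, seed=3)
print({k: round(v, 4) for k, v in report.pooled_metrics.items()})
print(round(report.pooled_auc, 4))
```

prints

```
{'accuracy': 0.9381, 'sensitivity': 0.9527, 'precision': 0.9256,
 'specificity': 0.9234, 'f1': 0.939}
0.9825
```

i.e. over the 3 × 296 held-out test windows the classifier recovers the
injected frontal-theta class difference almost perfectly: 93.8 % of
windows are labelled correctly, 95.3 % of depressed windows are detected
(sensitivity) and the ranking quality is AUC 0.98.  With no injected
effect the same experiment stays at chance (≈ 0.5) — see the methods note
for why that null calibration matters.

The fitted model itself follows the Model/Results pattern:

```python
results = sp.SparNetClassifier(region_tensors, labels, groups=subjects).fit()
print(results.summary())
```

```
SparNet classifier results
==========================================
regions (channels):      (12, 25, 12, 12, 12)
feature length:          40
SE attention:            on
trainable parameters:    1595
...
parameters per layer:
  branch0.se          144
  branch0.conv         61
  branch1.se          600
  ...
```

A command-line surface wraps the same pipeline:

```sh
sparnet simulate --n-mdd 24 --n-control 24 --seed 7 --effect F:theta:3.0 --out cohort
sparnet run --manifest cohort/manifest.csv --out results
sparnet featurize --manifest cohort/manifest.csv --out features
sparnet inspect features/mdd01.npz
```

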