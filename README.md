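# edemaeeg

Quantitative-EEG detection — and pre-radiographic *prediction* — of diffuse
cerebral edema in comatose survivors of cardiac arrest.

Diffuse cerebral edema is a common, often fatal complication of
hypoxic-ischemic brain injury. It is usually recognized late, on head CT or
after clinical deterioration, because imaging happens at irregular
intervals and the neurological exam of a sedated, cooled patient is
unreliable. Continuous EEG, however, is already running at the bedside of
most of these patients. As edema develops, the EEG background becomes
globally suppressed, delta-dominant, and burst-suppressed — a phenotype
that quantitative EEG features capture well. This package implements the
full analysis chain that turns that observation into a classifier, for
researchers in clinical neurophysiology and neurocritical care who want a
tested, reproducible reference pipeline.

## What it computes

For each patient, 18 bipolar derivations are standardized (double-banana
montage, 0.1–40 Hz zero-phase band-pass, 100 Hz resampling, rule-based
artifact rejection), and nine qEEG features are computed per derivation per
300-s epoch:

| feature | definition (per epoch x, sampling rate fs) |
|---|---|
| Shannon entropy | −Σ pᵢ log₂ pᵢ over a 64-bin amplitude histogram |
| Signal regularity | √( Σᵢ i²·s(i) / ((N²/3)·Σᵢ s(i)) ), s = sorted x², descending |
| Band power (δ, θ, α, β) | Welch PSD integrated over 0.5–4, 4–8, 8–13, 13–30 Hz |
| Alpha–delta ratio | P_α / (P_δ + ε) |
| Spike frequency | sharp outlier extrema (> 6 robust SD, width 20–140 ms) per minute |
| Burst-suppression ratio | fraction of time the smoothed envelope stays < 5 µV for ≥ 0.5 s |

A Transformer encoder (or LSTM) classifies the per-epoch feature sequence
into edema / no edema, trained with class-balanced augmented training sets
(noise at controlled SNR, channel shuffling, smooth time masking) and a
repeated-validation protocol; evaluation uses repeated class-balanced
train/test splits with median [IQR] AUC, accuracy, sensitivity and
specificity at threshold 0.5, Wilcoxon signed-rank model comparisons, and
permutation-sampling Shapley attribution of the nine features. The
prediction task matches each eligible edema case (more than 1 h of EEG
before first radiographic evidence) to a no-edema referent by
nearest-neighbor on age, sex, witnessed arrest and EEG timing, and
fine-tunes the detection model on pre-recognition EEG windows.

Because no clinical recordings are distributable, a seeded synthetic
cohort generator (`edemaeeg.synth`) produces EDF recordings plus metadata
with the statistical structure the analysis assumes — suppressed,
delta-dominant, burst-suppressed backgrounds for the edema class against
continuous mixed-frequency backgrounds, realistic covariate shifts, and
injected artifacts with known ground truth. Every stage of the pipeline is
tested against that generator and against independently coded oracles; see
`docs/methods.md` for the full model description.

## Worked example

A desk-scale run of the detection experiment (124 synthetic patients at
52.4 % edema prevalence, every arrest-relative clock shrunk 20×, 64 Hz
sampling, 10 replications × 30 training iterations):

```python
from edemaeeg import models, pipeline, synth

cfg = pipeline.RunConfig(time_scale=0.05, band_high_hz=31.0,
                         target_rate_hz=64.0, n_replications=10,
                         model=models.ModelConfig(n_iterations=30, seed=1),
                         seed=5)
synth_cfg = synth.SynthConfig(n_patients=124, sample_rate=64.0,
                              time_scale=0.05, seed=42)
records, tensors = pipeline.prepare_detection_cohort(synth_cfg, cfg)
results, summary = pipeline.run_detection(records, tensors, cfg)
print({m: round(summary[m]["median"], 3)
       for m in ("auc", "accuracy", "sensitivity", "specificity")})
```

```
{'auc': 1.0, 'accuracy': 1.0, 'sensitivity': 1.0, 'specificity': 1.0}
```

With the generator's wide default class separation the classifier is
expected to saturate: every replication's balanced 10 + 10 test set is
separated perfectly. The informative controls are the null cohort
(`synth.default_class_params("edema", separation=0.0)`), where the same
experiment must collapse to chance (median AUC 0.465 in the seed-1
acceptance run — nothing is learned when nothing is planted), and the
Shapley ranking, where the suppression-structure features the edema class
encodes — burst-suppression ratio, signal regularity, Shannon entropy —
carry the most attribution while the equalized theta/alpha/beta band
powers carry almost none.

The same stages are available from the shell:

```bash
edemaeeg simulate --n-patients 124 --time-scale 0.05 --seed 42 --out cohort/
edemaeeg run --task both --time-scale 0.05 --seed 5 --out runs/
```

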