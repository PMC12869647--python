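# Methods

`edemaeeg` implements an EEG-based pipeline for recognizing diffuse
cerebral edema after cardiac arrest: quantitative-EEG (qEEG) feature
extraction from standardized recordings, sequence classification with
Transformer or LSTM models, a replicated class-balanced evaluation
harness, Shapley feature attribution, and a matched case–referent analysis
that asks whether the classifier can flag edema from EEG windows that end
*before* the first radiographic evidence.  Because no clinical recordings
ship with the package, every stage is exercised against a seeded synthetic
cohort generator whose class structure mirrors the physiology the features
target.

## Signal model and preprocessing

Recordings are multichannel scalp EEG in microvolts with time measured in
decimal hours since return of spontaneous circulation (ROSC); analysis
windows are half-open `[start, end)`.  Preprocessing follows standard
clinical qEEG practice:

* **Montage** — longitudinal bipolar "double banana" (18 derivations from
  the 19-electrode 10–20 set).  Already-bipolar inputs pass through.
* **Filtering** — 0.1–40 Hz band-pass, 4th-order Butterworth applied
  forward–backward (zero phase).  The band edges are configurable; runs at
  reduced sampling rates use a correspondingly lower upper edge (e.g.
  0.1–31 Hz at 64 Hz sampling).
* **Resampling** — polyphase down-sampling to 100 Hz (or the recording
  rate, whichever is lower); up-sampling is refused.
* **Artifact rejection** — per-channel rules over fixed 10-s windows: a
  window is excluded (never interpolated) when max |amplitude| > 500 µV,
  its standard deviation falls below 0.1 µV (flatline), or any one-sample
  difference exceeds 100 µV (rapid change).  All four constants are
  configurable; the defaults are common clinical heuristics for the three
  rule families.  Note a windowed SD rule cannot represent flat runs much
  shorter than its window; the synthetic generator therefore injects
  flatlines that always blanket at least one full window.
* **Segments** — the detection task uses windows beginning 24 h
  post-arrest (4 h by default; 8/12/24 h variants and an early-EEG mode
  are config options).  The prediction task uses windows that end at
  min(recognition time, end of recording) and extend backward 4 or 8 h;
  a case needs strictly more than 1 h of EEG before recognition to be
  eligible (the strict boundary is a deliberate convention: a case with
  exactly 1.0 h is excluded).  Referent windows are placed at the matched
  case's arrest-relative times.  Partial coverage is allowed everywhere;
  uncovered epochs are recorded as missing.

## The nine qEEG features

Features are computed per derivation per non-overlapping 300-s epoch (a
4-h segment yields a 48-epoch sequence).  Fixed order: Shannon entropy,
signal regularity, delta/theta/alpha/beta band power, alpha–delta ratio,
spike frequency, burst-suppression ratio.

* **Shannon entropy** (bits): amplitude-histogram entropy with B = 64 bins
  over the epoch's observed range; constant epochs have entropy 0.  B
  trades bias for variance: smaller B saturates early, larger B inflates
  entropy of short epochs; 64 keeps the estimator's complexity fixed
  across epoch lengths.
* **Signal regularity** ∈ [0, 1]: with squared amplitudes sorted
  descending s(1..N), `q = sqrt( Σ i² s(i) / ((N²/3) Σ s(i)) )`.  A flat
  envelope keeps mass at high ranks (q → 1); a single spike gives
  q = √3/N.  All-zero epochs are defined as maximally regular.  This is a
  suppression-sensitivity statistic from the qEEG literature; the exact
  formula is pinned here because published descriptions vary.
* **Band power** (µV²): Welch-averaged periodogram (periodic Hann window,
  4-s segments, 50 % overlap, per-segment constant detrend) integrated
  over delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz.  The estimator
  is implemented in-house as one batched FFT over all epochs and verified
  against `scipy.signal.welch` to machine precision in the tests.
* **Alpha–delta ratio**: alpha power / (delta power + 1e-12).
* **Spike frequency** (events/min): local maxima of |x − median| exceeding
  6 robust SDs (1.4826·MAD) whose full width at half height lies in
  20–140 ms, with a 200 ms refractory period between counted events.
  Width is measured by linear interpolation at half the peak deviation.
* **Burst-suppression ratio** ∈ [0, 1]: the envelope is a 0.05-s moving
  average of |x|; suppression is any envelope run below 5 µV lasting at
  least 0.5 s; the BSR is suppressed time over epoch time.

Missing handling: an epoch is missing for a channel when more than half of
it is artifact-flagged or uncovered.  The detection task performs no
imputation (its cohorts are generated with full coverage); the prediction
task imputes each missing entry with the cohort mean of that feature
pooled over epochs, derivations and patients.  Before modeling, features
are z-scored per feature using training-set statistics only; masked
entries enter the models as 0, i.e. exactly the training mean.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, not
physiologically faithful EEG (no head modeling, seizure morphology, or
sedation pharmacokinetics):

* **Band-limited Gaussian noise** is synthesized by exact
  frequency-domain shaping (complex-Gaussian spectra on the band bins,
  one inverse FFT per channel), so each band component's expected RMS
  equals its configured weight analytically.
* **No-edema class** — continuous mixed-frequency background at RMS
  weights delta 5 / theta 6 / alpha 8 / beta 4 µV, with a slow (≈0.1 Hz)
  random amplitude envelope (depth 0.15, clipped to [0.5, 1.5]).
* **Edema class** — globally suppressed, delta-dominant, burst-suppressed
  background: a two-state semi-Markov burst/suppression envelope shared
  across channels (mean suppression dwell 5 s, burst dwell set so the
  long-run suppression fraction is 0.6); burst weights delta 25 µV with
  the non-delta weights scaled by 1/√(1 − suppression fraction) so their
  *time-averaged* power matches the no-edema class.  That scaling is
  deliberate: without it the duty cycle separates the classes through
  every band power, whereas the physiology this class emulates
  discriminates through delta dominance and suppression structure
  (entropy, regularity, burst-suppression ratio).  The suppression floor
  is fixed at 1.5 µV RMS — comfortably below the 5 µV BSR threshold so
  the configured suppression fraction is recoverable by the detector
  (delta-dominant spectra have high peak-to-RMS factors; a 2 µV floor
  already leaves ≈1.5 % of suppressed samples above threshold).
* **Between-patient heterogeneity** — per-patient log-normal gain on each
  band weight (σ = 0.25) and a log-normal multiplier on the
  burst/suppression dwell times (σ = 0.3).  Without it, ratio features
  have vanishing within-class variance and any single feature separates
  the classes almost deterministically, which no real cohort does.
* A `separation` knob interpolates the edema class toward the no-edema
  class; 0 makes the classes identical (the null cohort used to check
  that the pipeline finds nothing when nothing is planted).
* **Channels** — 19 referential 10–20 channels (or 18 bipolar derivations
  directly); channels share the class process (burst state, slow
  envelope, and a common background component at correlation 0.6) plus
  independent channel noise.
* **Covariates** — drawn per class in the directions of the cohort table
  the study design describes: edema patients younger (−8 y shift on a
  56 ± 13 y base), less often witnessed (41.5 % vs 66.1 %), more often
  out-of-hospital arrests (92.3 % vs 70.7 %), earlier EEG starts
  (log-normal, medians 17.8 vs 22.1 h, σ = 0.45).  EEG start delays are
  truncated to [4, 22] h so monitoring is always running before the 24-h
  analysis window opens — matching the detection cohort's "no imputation
  required" condition.  Recognition times for edema patients are drawn so
  a configurable fraction (default 60 %) has more than 1 h of EEG before
  recognition, truncated to [1, 240] h post-arrest.
* **Artifacts** — three kinds with known intervals for detector testing:
  600 µV raised-cosine transients (0.3 s), near-zero flatlines (20–40 s),
  and 250 µV step discontinuities (held 2–5 s).  Counts are Poisson at
  configured per-hour rates; intervals never overlap within a channel.
* **Determinism** — the cohort seed streams into per-patient sub-seeds by
  stable hashing of the patient id, so a patient's record is independent
  of cohort size and generation order.

What passing tests on these cohorts show: the pipeline recovers planted
class structure through the full preprocessing → features → model →
evaluation chain, and recovers nothing when none is planted.  What they do
not show: performance on real post-arrest EEG, whose artifacts,
medication effects, and between-patient heterogeneity the generator does
not emulate.

### Scaled study conditions

End-to-end runs shrink every arrest-relative clock by a single
`time_scale` factor (0.05 in the shipped tests and acceptance script:
15-s epochs instead of 300-s, a 0.2-h segment standing for the 4-h one,
recordings of ≈1.5 h) and sample at 64 Hz with a 0.1–31 Hz band.
Sequence structure is preserved exactly (48 epochs per 4-h-analogue
segment); waveform morphology and all feature-internal constants stay in
real seconds, so every feature operates on physiological signals.  The
scale is bounded below by the BSR's 10-s minimum epoch.

## Models and training

Both classifiers consume the per-epoch sequence of 18 × 9 z-scored
features (flattened to 162 inputs per epoch) and emit one edema
probability per patient.

* **Transformer** — linear input projection to 64 dims, sinusoidal
  positional encoding, 2 pre-norm encoder blocks (4-head self-attention +
  2× feed-forward, dropout 0.1), mean-pooling over epochs, linear head.
* **LSTM** — 2 stacked layers of width 64, final hidden state, linear
  head; forget-gate bias initialized to 1.

These are the smallest configurations that pass the capacity checks
(near-zero training loss on 4 samples within 500 iterations).  Training
uses Adam (lr 1e-3), batch size 16, binary cross-entropy on logits.  One
*iteration* = draw a fresh validation subset (20 % of training patients,
drawn by patient so augmented copies follow their source), run one
minibatch pass over the remainder, and score validation loss; the
parameter state with the best validation loss over all iterations (150 at
full scale, 30 in the scaled runs) is retained.  Fine-tuning for the
prediction task restarts from a trained detection model at 0.1× the
learning rate with the same protocol, tuning the full network (no layers
frozen).  All stochastic operations consume explicit seeds; runs are
bitwise reproducible per platform/build.

The networks run on a small in-house reverse-mode autodiff over numpy
(`edemaeeg.autodiff`), gradient-checked against central finite differences
in the test suite.

## Augmentation

Three transforms, applied only to training patients, with provenance links
so split hygiene can keep augmented copies out of test and validation
sets: Gaussian noise at a target SNR (default 20 dB), channel shuffling
(within-hemisphere by default), and a smooth time mask (60 s at 0, 5-s
raised-cosine ramps).  The canonical mode perturbs raw signals and
re-extracts features; a feature-space fast mode (noise at SNR on feature
values, within-hemisphere derivation permutation, raised-cosine blending
of an epoch run toward feature means) approximates it at a fraction of
the cost and is what the replicated scaled experiments use.  Balancing
upsamples the minority class to the majority count with augmented copies;
originals are always retained.

## Evaluation harness

* **Detection splits** — per replication, `round(0.16·N)/2` patients per
  class are drawn for a class-balanced test set (10 + 10 at N = 124);
  everyone else trains; 30 replications (10 in scaled runs) with
  freshly drawn test sets.  Training never receives test tensors or
  labels, by interface.
* **Metrics** — AUC as the Mann–Whitney concordance probability (ties
  half), accuracy/sensitivity/specificity at threshold 0.5; medians with
  IQRs by linear-interpolation percentiles (small-n IQRs are
  method-sensitive, hence pinned).
* **Model comparison** — two-sided Wilcoxon signed-rank on paired
  per-replication differences; zero differences dropped; exact null by
  dynamic programming over sign patterns (midranks for ties) up to 25
  nonzero differences, tie-corrected normal approximation (no continuity
  correction) beyond.
* **Attribution** — permutation-sampling Shapley values with the
  training-mean tensor as background, grouped to the nine named features
  (summing over epochs and derivations) because that is the granularity
  at which importance is interpreted.  Per-permutation contributions
  telescope, so per-sample attributions satisfy the efficiency property
  exactly; rankings report mean |value| per feature, averaged over
  replications.  The pipeline attributes the model's *logit* rather than
  its probability: on well-separated cohorts the probability saturates
  and feature-flip effects vanish, while log-odds contributions remain
  informative (the usual choice for classifier explanations).
* **Matching** — greedy 1:1 nearest-neighbor without replacement on age,
  sex, witnessed status and arrest-to-EEG time: continuous covariates
  z-scored (over cases + pool) with Euclidean distance; each mismatched
  binary covariate adds a fixed 2.0 to the squared standardized distance,
  which forces exact binary matches whenever available at typical
  covariate spreads; cases are processed in seeded random order.
* **Prediction splits** — by matched pair (case and referent travel
  together), 58 % of pairs to training.
* **Secondary analyses** — subgroup metrics by predicate (e.g. OHCA vs
  IHCA) on test patients, and an indeterminate-label policy: the primary
  analysis excludes indeterminate patients; the secondary relabels them
  as no-edema.

## Interfaces

EDF is the sole raw-signal interchange format: a minimal 16-bit EDF
writer (1-s records, physical units µV) lives in `edemaeeg.pipeline`, and
reading goes through `mne`; round trips are exact up to 16-bit
quantization.  Cohorts export as one EDF per patient plus a metadata CSV
(`id, class, age, sex, witnessed, ohca, t_eeg_start_h, t_edema_h`) and a
YAML config echo.  Feature tensors serialize to a flat CSV and models to
a versioned npz container with a JSON config alongside.  `RunConfig`
round-trips losslessly through YAML and rejects unknown keys; every
output directory is named by a hash of the config that produced it, so a
changed configuration never silently overwrites an earlier run.

## Numerical choices and edge cases

* Constant epochs: entropy 0; all-zero epochs: regularity 1.0, BSR 1.0.
* Alpha–delta ratio guards division by zero with ε = 1e-12.
* Zero-power channels receive augmentation noise at an absolute floor
  (0.1 µV RMS).
* Empty segments produce all-missing tensors (valid input to the
  prediction task's imputation; an error only if a feature is missing
  cohort-wide).
* Degenerate validation draws that would leave single-class fitting data
  fall back to fitting on the full training set for that iteration.
* AUC is NaN (not an exception) for single-class subgroups so subgroup
  analyses degrade gracefully.

## Known limitations

* The generator's class phenotypes are assumptions tuned for testability,
  not estimates from any clinical dataset; real post-arrest EEG is far
  more heterogeneous.
* Feature definitions (entropy binning, regularity formula, spike
  sharpness window, BSR thresholds) follow common clinical conventions
  but published variants differ; all constants are configurable.
* The artifact rules operate per window; sub-window artifacts and
  physiological artifacts (EMG, sweat, electrode pops with slow drifts)
  are out of scope, as are ICA-style corrections.
* Wilcoxon p-values on 10–30 replications of the same cohort are
  comparisons of paired experimental arms, not population inferences.
* The in-house autodiff favors clarity over speed; it is adequate for the
  model sizes here and nothing larger.
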