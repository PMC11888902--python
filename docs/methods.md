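# Methods

## The problem and the data model

Ballistocardiography measures the recoil forces of cardiac ejection through
pressure sensors under a mattress. A recording here is a uniformly sampled
multi-channel time series at 100 Hz with a recording-level label
(hypertensive = 1, normotensive = 0). Real bed-sensor data of this kind is
rarely shareable, so the package ships a synthetic generator that emulates
its salient structure; everything downstream is agnostic to whether a
recording came from the generator or from a CSV exported by an acquisition
system.

## Synthetic generator

Each recording is a sum of independent components:

* **Beat train.** A recording-level heart rate is drawn from the class
  distribution (normotensive 73.6 ± 8.3 bpm, hypertensive 77.1 ± 9.2 bpm —
  typical cohort statistics for middle-aged adults, used purely as
  simulation parameters) and clipped to [30, 200]. Beats are placed
  quasi-periodically: successive gaps are the mean period times
  `1 + jitter·N(0,1)` with jitter 0.05, floored at 20% of the period. Each
  beat contributes a Gaussian-windowed cosine (centre 7 Hz, width σ = 40 ms)
  — a minimal stand-in for the BCG IJK complex that concentrates energy in
  the 1–50 Hz band the preprocessing targets, with no claim of
  morphological fidelity.
* **Respiration and drift.** One sinusoid at 0.25 Hz (amplitude 0.3) with a
  random phase models respiratory wander; a second at a random
  0.01–0.05 Hz frequency (amplitude 0.2) models slow postural drift.
* **Noise and artifacts.** White Gaussian noise (σ = 0.1) per channel, plus
  single-sample spikes of ±5.0 arriving as a Poisson process at 2/min,
  shared across channels as whole-body movements would be.
* **Channels.** Two sensors share the physiological components with random
  gains in [0.8, 1.0] and independent noise.

Class separation enters through heart rate **and** beat amplitude
(normotensive 1.0, hypertensive 1.4). Because every channel is later
min–max normalized, an absolute gain difference would vanish; what survives
normalization is the beat-to-background amplitude *ratio*, which moves the
shape statistics (kurtosis, skewness, IQR) of the windows. The 1.4 factor
was chosen once as a separation that is learnable but not trivial at the
default noise level. `SyntheticConfig.without_class_separation()` gives both
classes the normotensive parameters for null experiments.

What the generator does **not** model: realistic IJK morphology and its
beat-to-beat variability, heart-rate variability structure (only white
jitter), sensor nonlinearity, posture changes, or any true hemodynamic
link between blood pressure and the waveform. Passing tests therefore show
the pipeline recovers the *injected* class differences; they say nothing
about detecting hypertension in real recordings.

Determinism: every stochastic quantity comes from one `numpy` generator
seeded per recording via `SeedSequence(cfg.seed).spawn(...)`, so a dataset
is a pure function of the config.

## Preprocessing

The chain is fixed in order: high-pass 1 Hz → low-pass 50 Hz → anomaly
removal → high-pass 0.5 Hz (baseline) → min–max to [0, 1]. Choices:

* **Filter family.** Order-4 Butterworth, applied forward–backward
  (`sosfiltfilt`), the standard biosignal compromise: maximally flat
  passband and exactly zero phase so beat timing is preserved. The
  effective magnitude response is the square of the one-pass response.
* **Nyquist clamp.** A 50 Hz cutoff at 100 Hz sampling sits exactly at
  Nyquist and is unrealizable; cutoffs ≥ Nyquist are clamped to
  0.99·Nyquist (49.5 Hz) with a warning. This keeps the design well-posed
  while preserving the intent (suppress high-frequency noise).
* **Anomaly rule.** Per channel, over the whole recording, flag samples
  strictly above `mean + k·std` (k = 2, population σ). The rule is
  deliberately one-sided — the canonical artifact is a large positive
  pressure spike — and negative excursions pass untouched. Flagged samples
  are replaced by linear interpolation between the nearest unflagged
  neighbours (edges extend the nearest value), preserving the uniform grid
  the later filters require. A literal `drop` mode deletes flagged rows;
  it breaks uniform sampling, and downstream filters then refuse the
  recording by design.
* **Normalization** is per recording and per channel; a constant channel
  maps to all zeros by convention.

## Features

Recordings are cut into non-overlapping windows of `floor(window_s · fs)`
samples from sample 0 (default 30 s → 3,000 samples at 100 Hz); a trailing
remainder is dropped. Eleven statistics per channel, with conventions fixed
so results are bit-stable:

* moments use divisor *n* (population); skewness is m₃/m₂^{3/2} and
  kurtosis m₄/m₂² − 3 (Fisher excess), both without small-sample
  correction; constant windows get skewness = kurtosis = 0;
* quartiles use linear interpolation between order statistics
  (`numpy.quantile` default).

Two channels × 11 statistics → 22 features per segment, concatenated rather
than channel-averaged to preserve per-sensor information. Standardization
(zero mean, unit variance) is always fitted on the training rows only and
applied unchanged to evaluation rows.

## Classifiers

The two neural models run on `bcgkit.nn`, a small reverse-mode autodiff
engine over numpy arrays written for this package (no deep-learning
framework dependency). Gradients of every layer are verified against
central finite differences in the test suite; parameters initialise from
U(±1/√fan_in) with a seeded generator, so training is bit-reproducible.

* **FC+LSTM.** FC(d→512) → ReLU → FC(512→256), the projection treated as a
  length-1 sequence into a 2-layer, 128-unit LSTM; the final hidden state
  passes FC(128→64) → Dropout(0.1) → FC(64→2). There is deliberately no
  nonlinearity between the last two linear maps: the model follows its
  defining equations as stated. Since the published formulation never
  defines a tokenization for the "reshape" into the LSTM, sequence length 1
  is the default; `seq_len` > 1 splits the 256-vector into tokens instead.
  Training: cross-entropy, Adam lr 0.001, ×0.1 every 10 epochs, 50 epochs,
  batch 32.
* **Transformer.** Linear embed to 256, dropout 0.1, three post-norm
  encoder layers (4 heads, 512-unit feed-forward, dropout 0.1), mean
  pooling over tokens (identity at length 1), linear head. Adam lr 0.0005
  with a plateau schedule (×0.5 after 3 epochs without training-loss
  improvement — no validation split is carved out for scheduling). At
  sequence length 1 self-attention reduces to a learned per-token map;
  positional encoding is omitted as it would be meaningless there.
* **Ensembles.** Stacking fits RF, GB and XGBoost (100 estimators each) and
  a logistic-regression meta-learner on their out-of-fold predicted
  probabilities (5-fold cross-fitting), so the meta-learner never sees
  probabilities from a base that trained on the same rows; bases are then
  refitted on the full training set for inference. Soft voting averages
  the three bases' probabilities uniformly; argmax ties resolve to the
  lower class index. XGBoost is also exposed standalone.

## Validation and metrics

Splits are stratified and, by default, **group-aware**: partitions operate
on source recordings, so the ~10 near-duplicate segments of one recording
can never straddle a train/test boundary. This is the single choice that
most affects reported scores; `group_aware=False` reproduces segment-level
splitting for comparison. Hold-out supports any test fraction (0.5 and 0.25
are the conventional settings); k-fold uses `StratifiedGroupKFold`.
Fold metrics are aggregated by unweighted mean. One consequence worth
knowing: on label-free (null) data, group-aware CV accuracy can dip
noticeably *below* 0.5 for flexible models — they latch onto spurious
recording-level structure that anti-generalizes to held-out recordings.
This pessimistic bias is a property of grouped validation, not a defect.

All metrics derive from the confusion matrix with hypertensive = 1
positive. Cohen's κ is (P₀ − Pₑ)/(1 − Pₑ); if both raters are constant and
identical (Pₑ = 1) it is defined as 1 for perfect agreement, else 0, with a
warning. Degenerate 0/0 ratios (e.g. precision with no positive
predictions) return 0 with a warning instead of raising, so CV loops
survive degenerate folds. The ROC curve sweeps all distinct score
thresholds from (0,0) to (1,1); trapezoidal integration equals the
Mann–Whitney statistic with ties counted ½ (asserted to 1e-12 in tests).
McNemar's test uses χ² = (b−c)²/(b+c) on the discordant counts with a
1-df chi-square p-value; the continuity correction is off by default and
available as a flag; b + c = 0 yields χ² = 0, p = 1.

## Problem sizes and numerical choices

The end-to-end experiments use 30 recordings per class of 5 minutes each →
600 segments × 22 features, a size at which every model trains in seconds
to a few minutes on one CPU while leaving enough recordings (60) for
group-aware splits. Examples use smaller sets (10–12 recordings per class)
for faster narration. Tolerances: uniform-grid check 1 ns; probability
normalization 1e-9; metric-vs-oracle agreement 1e-10; filter warm-up
regions are excluded when measuring tone amplitudes, and amplitudes are
estimated as √2·RMS because coarse sample grids miss sine crests.

## Known limitations

* The synthetic beat is a single fixed wavelet; models that exploit
  morphology beyond amplitude/rate statistics cannot be distinguished here.
* Only time-domain window statistics are implemented; no spectral or
  beat-to-beat (HRV) features.
* The anomaly rule is one-sided and recording-global; a long recording with
  drifting variance may over- or under-flag locally.
* Binary labels only; no regression toward actual blood-pressure values.
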