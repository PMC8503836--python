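# Methods

## Overview

`ppgsleep` implements an automatic sleep-staging pipeline that uses only the
photoplethysmogram (PPG), and the downstream analysis of sleep fragmentation
across obstructive sleep apnea (OSA) severity groups. The pipeline has four
stages:

1. **Preprocessing** — raw PPG is decimated to 32 Hz behind an order-8
   Chebyshev type I anti-aliasing filter, z-score normalized over the whole
   recording, and cut into 30-s windows (960 samples) on a grid with
   epoch-to-epoch interval d ∈ {30, 15, 5, 1} s.
2. **Staging network** — a 1D EfficientNet CNN applied per window, a
   bidirectional LSTM across the night, and a dense softmax head for 3, 4 or
   5 stage classes.
3. **Hypnogram densification** — running inference with d < 30 yields
   overlapping windows and a denser hypnogram without retraining.
4. **Fragmentation analysis** — per-patient mean continuous sleep feeds a
   Cox proportional-hazards model with one-hot OSA-severity covariates, plus
   per-category Kaplan–Meier curves.

A seeded simulator generates synthetic cohorts (stage sequences with
severity-dependent wake intrusions, and stage-separable PPG) so the whole
pipeline is exercised end-to-end without clinical data.

## Preprocessing conventions

The decimator is `scipy.signal.decimate` with `ftype="iir"`: an order-8
Chebyshev type I low-pass with 0.05 dB passband ripple, cutoff at 0.8× the
output Nyquist, applied forward–backward (zero phase) so pulse landmarks are
not shifted. Zero-phase filtering and the ripple/cutoff values are package
conventions — standard decimation practice — not constraints inherited from
the staging method itself. Note that an even-order Chebyshev I ripples
*down* at DC, so the twice-applied DC gain is exactly 10^(−0.005) ≈ 0.9886;
tests assert against this closed form.

Normalization is population-SD z-scoring of the whole downsampled
recording (downsample first, then normalize). A zero-variance recording
yields all zeros and a warning flag. Time is 0-based seconds from recording
start; windows are half-open `[i·d, i·d + 30)`; with n labels the trailing
`30 − d` seconds carry no label; a trailing remainder shorter than one step
is dropped, giving `n = floor((T − 30)/d) + 1` windows.

## The staging network

`default_spec()` reproduces the published architecture: stem Conv(k=11, s=3,
32 ch, no padding; 960 → 317), seven MBConv stages with
(kernel, stride, channels, expand, repeats) =
(3,1,16,1,1), (5,2,24,6,2), (3,2,24,6,2), (5,2,32,6,3), (5,2,48,6,4),
(5,2,64,6,5), (3,1,128,6,1), all with squeeze-and-excitation ratio 0.25 and
"same" padding (stride-2 stages halve length by ceiling:
317 → 159 → 80 → 40 → 20 → 10), then a 1×1 convolution to 512 channels and
global average pooling. Swish activation inside the CNN, ReLU in the dense
layer, softmax output. The BiLSTM has 128 units per direction (input 512,
output 256); the dense layer 32 units.

Conventions were fixed by requiring the component parameter counts to equal
the published table exactly (CNN 696,156; BiLSTM 656,384; dense 8,224;
5-class head 165):

* convolutions are bias-free and followed by batch normalization;
* batch-norm contributes 4 numbers per channel — the counts *include* the
  non-trainable moving statistics (this resolves an ambiguity in the printed
  table: they are included);
* the squeeze-and-excitation reduction width is
  `int(block_input_channels × 0.25)` with biased 1×1 projections;
* within a stage, only the first repeat carries the stride and the channel
  change; residual connections exist only where stride = 1 and
  cin = cout (the MobileNetV2 rule);
* the BiLSTM uses the combined parameterization
  `2 × 4 × ((512 + 128) × 128 + 128) = 656,384`.

The network is implemented directly on NumPy (forward and reverse-mode
gradients, momentum SGD), with gradient correctness checked against central
finite differences in the development suite. Class order is fixed as
(W, N1, N2, N3, R) — merged schemes (W, LIGHT, N3, R) and (W, NREM, R) —
and argmax ties break toward the lower index. Dropout defaults to 0 and
adds no parameters.

`compact_spec()` is a width/depth-reduced variant of the same design
(8-channel stem, four MBConv stages with expand ratio 4, 64 features,
32-unit LSTM; ≈48k parameters) used for CPU-scale training experiments.

## Training protocol

Cross-entropy is minimized with plain momentum SGD (momentum 0.9), batch =
one full night per step; the optimizer choice is the native setting of the
one-cycle methodology and is configurable. Training always uses
non-overlapping 30-s epochs, one label per window; overlap is an
inference-time device only. The learning rate follows the one-cycle policy:
linear ramp `lr_min → lr_max` over `ramp` epochs, linear ramp back down over
the same number, then an exponential tail of 20 epochs ending at
`lr_min/100`. A learning-rate range test (exponentially spaced one-step
probes; suggested `lr_max` at the steepest descent of the smoothed loss,
`lr_min = lr_max/10`) chooses the cycle bounds. The ramp length has no
canonical default and is a required configuration value. Model selection
returns the weights of the epoch with minimum validation cross-entropy;
train/validation splits are by patient, never by epoch. Fine-tuning
multiplies all schedule rates by `lr_scale` and starts from pretrained
weights; a class-count mismatch re-initializes only the output head (with a
warning).

Batch normalization uses momentum 0.9 for its moving statistics — with
full-night batches and CPU-scale runs (tens to hundreds of update steps)
the statistics must converge within a few epochs for validation-mode
inference to reflect training-mode behaviour.

## Densified inference

For d < 30 the window grid is processed as `30/d` interleaved subsequences,
one per phase offset, each with windows spaced 30 s apart — the spacing the
recurrent layer was trained on. Two consequences: the 30-s hypnogram is an
exact subsequence of every finer hypnogram (identical labels at shared
windows), and inference cost scales with `30/d`, mirroring the reported
~6× inference time at d = 5. Each window's stage is attributed to its
leading d seconds. When hypnograms at different intervals are compared, the
coarser one is upsampled by label repetition and the pair truncated to the
common length (a convention; the underlying method defines no alignment).

## Sleep parameters and agreement

With n labels at interval d (minutes per label d/60): TRT = n·d/60,
TST = non-wake count × d/60, SE = 100·TST/TRT, sleep onset = first non-wake
label, WASO = wake time from onset to the end of the recording. No lights-on
annotation exists in the data model, so WASO runs to the end of recording —
a documented divergence from the AASM lights-off/on convention. Stage
percentages are relative to TST and sum to 100 when TST > 0; wake percentage
is relative to TRT. An all-wake hypnogram has undefined onset and absent
stage percentages. Agreement metrics (confusion matrix with the reference
on rows, accuracy, per-class precision/recall/F1, Cohen's κ with
marginal-product expected agreement) are computed with scikit-learn; classes
absent from both scorings are reported as absent and excluded from macro
summaries. Group comparisons use the Wilcoxon signed-rank test (paired) and
the Mann–Whitney U test (independent), two-sided, exact for small samples
and asymptotic (with continuity correction for Wilcoxon) otherwise, with a
Shapiro–Wilk normality check exposed alongside. All-tied paired differences
are flagged degenerate with p = 1 by convention.

## Fragmentation survival analysis

Continuous sleep is a maximal run of consecutive non-wake labels (runs
touching the recording edges count); its per-patient arithmetic mean is the
time-to-event. Every patient is an event — the analysis treats mean
continuous sleep as fully observed, so there is no censoring mechanism.
Patients with zero sleep are excluded and logged rather than assigned a
degenerate zero time. OSA severity comes from the AHI (no < 5 ≤ mild < 15 ≤
moderate < 30 ≤ severe), one-hot encoded against the non-OSA reference.
Cox fits use lifelines with Efron tie handling (ties are common at coarse d;
Efron is the more accurate standard choice) and a tightened Newton stopping
tolerance (1e-9) so coefficients agree with an independent maximization of
the Efron partial likelihood to 1e-4 (asserted in the tests on toy tables).
Kaplan–Meier curves use the product-limit estimator with lifelines'
log-log (exponential) Greenwood 95% bands. The 1-s interval is excluded
from survival analysis by default: densified staging at 1 s oscillates
between sleep and wake too rapidly to represent sleep architecture, and no
quantitative exclusion rule exists for it.

One empirical caution, visible in the test suite: under majority-vote
scoring of 30-s windows, the detected mean continuous sleep is not strictly
monotone in d between adjacent fine intervals — wake that is already
detected at a coarse interval occupies *less* labelled time at a finer one
(the label covers only the leading d seconds), which can slightly raise the
mean. The dominant effect of densification — newly detected short wake
splitting runs — lowers the mean from d = 30 to d = 5, and that comparison
is what the tests assert.

## The synthetic cohort generator

The generator emulates the two properties the analyses need; all numeric
defaults below are the package's own choices, documented here — the staging
method itself prescribes no physiology.

**Stage sequences** are semi-Markov bout processes over {W, N1, N2, N3, R}
at 1-s resolution: an initial wake-to-sleep onset segment (exponential, mean
600 s, clipped to [60 s, T − 1800 s]), then exponential bouts (means: W 2,
N1 2, N2 12, N3 12, R 15 minutes, floored at 30 s) with a fixed transition
matrix following the typical cycle order W → N1 → N2 → N3 → N2 → R. On top,
a Poisson process injects wake intrusions after sleep onset at a
severity-dependent rate (defaults 2, 8, 20, 40 events/h for
no/mild/moderate/severe, in the range of clinical arousal indices) with
exponential durations of mean 15 s (floored at 2 s) — often shorter than a
30-s scoring epoch, the regime densification targets. Each night's rate is
additionally dispersed by a mean-one lognormal factor (σ = 0.6) so severity
distributions overlap as clinical ones do; without this overlap the fitted
hazard ratios are implausibly extreme.

**PPG waveforms** are trains of stereotyped two-Gaussian pulses (systolic
peak + dicrotic hump) with per-stage inter-beat interval, variability and
amplitude: mean IBI 0.85/0.95/1.00/1.05/0.88 s and SD
0.070/0.050/0.040/0.020/0.080 s for W/N1/N2/N3/R — wake and REM carry the
largest beat-to-beat variability, REM a fast pulse, mimicking sympathetic
activation — with amplitudes 1.0/1.1/1.2/1.3/0.95, a respiratory baseline
(0.25 amplitude, 0.19–0.26 Hz by stage, phase-continuous across stage
changes), 2-s movement-artifact noise bursts during wake (3/min), and a
0.05-SD white noise floor. AHI is *sampled* from the category's range
(0–5 / 5–15 / 15–30 / 30–60), never computed from events — respiratory
event waveforms, SpO2 and realistic PPG morphology beyond stage-separable
statistics are out of scope. 30-s training labels are majority votes over
the dense truth, ties broken toward the earlier-starting stage.

What passing tests therefore show: the pipeline recovers stage structure
and severity ordering when stages are separable in pulse statistics and
fragmentation is Poisson-like. They do not show robustness to real PPG
morphology, sensor artifacts, arrhythmia, or scorer disagreement.

## Problem sizes used in the test suite

CPU-scale conditions chosen for the shipped experiments: the end-to-end
training check uses 50 one-hour nights at 64 Hz (40 training, 10 held-out)
with the compact architecture and a short one-cycle schedule (ramp 3,
tail 2), asserting held-out 3-class accuracy above the majority-class
prevalence of the simulated mix. The fragmentation check uses 4 × 25
two-hour nights analysed at d = 30/15/5 via majority-vote scoring of the
dense truth (the model-free path of `fragmentation_analysis`), asserting
strictly increasing hazard ratios mild < moderate < severe at every
interval and a severe/mild HR spread at d = 5 no smaller than at d = 30.
Cox recovery uses 200 replicates of two-group exponential data
(true HR 2, n = 150/group), asserting median ĤR in [1.8, 2.2] and ~95%
CI coverage.

## Known limitations

* The NumPy network trains full-width models impractically slowly; the
  full-width spec is exercised for construction, counting and inference,
  training experiments use the compact variant.
* Exact bit-reproducibility holds within this BLAS/NumPy stack; across
  different BLAS builds, floating-point reductions may differ in the last
  bits.
* The simulator's stage transitions do not model time-of-night structure
  (REM pressure, deep-sleep decline), only run-length statistics.
* EDF output is minimal (one channel, 16-bit, 1-s records, whole-second
  durations); EDF+ annotations are not written.
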