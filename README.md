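# ppgsleep

Automatic sleep staging from the photoplethysmogram (PPG), and survival
analysis of the sleep fragmentation caused by obstructive sleep apnea (OSA).

Polysomnography with EEG is the clinical standard for scoring sleep, but it
is laborious, and home sleep-apnea tests usually record no EEG at all — while
nearly all of them record a PPG. Because autonomic activity differs between
wake, NREM and REM sleep, the pulse waveform carries enough information to
stage sleep. `ppgsleep` is for researchers in computational sleep medicine
who want a tested, self-contained implementation of that idea: a deep
staging model, densified hypnograms from overlapping epochs, standard sleep
parameters, and Cox/Kaplan–Meier fragmentation analysis — plus a seeded
simulator so everything runs end-to-end without clinical data.

## The model and the statistic

**Staging network.** Thirty-second windows of 32-Hz PPG (960 samples) are
encoded by a 1D EfficientNet: stem Conv(k=11, s=3) → seven MBConv stages
(depthwise-separable expansion convolutions, squeeze-and-excitation 0.25,
Swish) → 1×1 conv to 512 features → global average pooling. A bidirectional
LSTM (128 units/direction) integrates the whole night of per-epoch features,
and dense layers (32 ReLU → softmax) emit per-epoch probabilities over
{W, N1, N2, N3, R} (or merged 4-/3-class schemes). Component parameter
counts of the full model: CNN 696,156; BiLSTM 656,384; dense 8,224; 5-class
head 165. Training uses cross-entropy with one-cycle momentum SGD and a
learning-rate range test; fine-tuning reuses pretrained weights at reduced
rates. The network (forward and backward passes) is implemented directly on
NumPy.

**Densification.** Predicting with epoch-to-epoch interval d ∈ {15, 5, 1} s
overlaps the 30-s windows (e.g. d = 5 ⇔ 25-s overlap) and yields a denser
hypnogram from the same model — short awakenings that straddle two
conventional epochs become visible.

**Fragmentation statistic.** For each patient, continuous sleep runs are the
maximal stretches of consecutive non-wake labels; their mean is the "time to
event" of a Cox proportional-hazards model with one-hot OSA severity
(AHI < 5 reference; 5–15 mild, 15–30 moderate, ≥ 30 severe):

    h_i(t) = h0(t) · exp(β_mild x_mild + β_mod x_mod + β_sev x_sev)

Hazard ratios exp(β) > 1 mean sleep runs end sooner than in the non-OSA
group. Kaplan–Meier curves show the fraction of patients whose mean
continuous sleep exceeds t minutes.

## Worked example

```python
import numpy as np
import ppgsleep as pp
from ppgsleep.simulate import densify_truth

# a synthetic cohort: 25 nights per OSA severity category, 2-h nights
spec = pp.CohortSpec(n_per_category=(25, 25, 25, 25), duration_s=7200, seed=101)
cohort = pp.simulate_cohort(spec, with_ppg=False)

hyps = {d: [densify_truth(r.dense_stages, d, patient_id=r.patient_id)
            for r in cohort] for d in (30, 15, 5)}
ahi = {r.patient_id: r.ahi for r in cohort}
results = pp.fragmentation_analysis(hyps, ahi)
for d in (30, 15, 5):
    hr = results[d].cox.hr
    print(d, {k: round(v, 2) for k, v in hr.items()})
```

prints

```
30 {'mild': 3.88, 'moderate': 12.19, 'severe': 51.44}
15 {'mild': 4.53, 'moderate': 20.23, 'severe': 66.9}
5 {'mild': 4.39, 'moderate': 19.05, 'severe': 69.14}
```

Hazard ratios increase with OSA severity at every interval, and the spread
between severe and mild widens as the hypnogram gets denser (severe/mild
13.3 at 30 s vs 15.8 at 5 s here): denser hypnograms catch the short wake
intrusions that 30-s epochs smooth over, and they are concentrated in the
more severe groups.

The model side:

```python
model = pp.SleepStager(pp.default_spec(), n_classes=5)
print(model.describe())
```

```
component        output    #params
cnn          (Any, 512)    696,156
rnn          (Any, 256)    656,384
dense         (Any, 32)      8,224
output         (Any, 5)        165
total                    1,360,929
```

A CLI mirrors the workflow: `ppgsleep simulate | train | predict | agree |
analyze | describe-model` (see `ppgsleep --help`).

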