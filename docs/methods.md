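# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, and what the synthetic benchmark does and
does not demonstrate.

## Problem setting and model

Quality grading of wearable ECG/respiration windows is cast as anomaly
detection: an isolation forest is trained on unlabeled windows drawn
overwhelmingly from usable signal, so degraded windows — being few and
different — isolate in short paths and receive high anomaly scores. The
score axis is then cut into three grades by two thresholds calibrated on
a small labeled set. The semisupervised split of labor is the point:
the expensive part (learning what normal signal looks like) needs no
labels, and the labeled part (two scalars) needs only hundreds.

Assumptions inherited from the isolation-forest premise:

* degraded windows are a minority of the training stream (the default
  training mixture is 90/5/5 good/acceptable/unacceptable);
* the training stream covers the variety of *normal* signal (heart and
  breathing rates, mild wander and mains residue), otherwise novel but
  clean patterns score as anomalous.

Grades are ordered, and the score is treated as a monotone quality axis.
The middle (acceptable) grade overlaps both neighbours in score space
and is the hardest class by a wide margin — visible in every confusion
matrix the package prints; accuracy is carried by the dominant good
class and the well-separated unacceptable class.

## Observation windows and conditioning

Windows are 10 s (ECG) and 30 s (respiration); both are long enough to
hold several beats/breaths and short enough that quality is roughly
homogeneous. Default sampling rates are 200 Hz and 25 Hz (configurable).
Each raw window passes through a fixed chain: zero-phase order-4
Butterworth band-pass (ECG 0.5–40 Hz; respiration 0.05–1 Hz; baseline
removal is the high-pass edge), robust outlier clipping at
median ± 5 × 1.4826·MAD (a no-op on constant windows), then per-window
z-scoring. Windows are conditioned independently, so batch and
streaming give identical results. A window whose pre-normalization SD
falls below 1e−6 is flagged flatline, skips feature extraction
(receiving a documented sentinel vector) and is forced unacceptable at
classification time: full-window signal loss must never look clean, and
after z-scoring it otherwise would.

## Features

ECG (8): skewness, kurtosis (population convention, non-excess — a
Gaussian window gives kurtosis 3), mean and max adjacent-beat DTW,
R-peak count deviation from the window-median rate, max/median
peak-to-peak amplitude over 1 s subwindows, QRS-band (5–15 Hz) power
fraction, and >20 Hz power fraction.

Respiration (18): the moments; mean/max/SD adjacent-breath DTW; breath
count; breath-period mean/SD/CV; peak-amplitude mean/SD/CV;
peak-trough asymmetry; zero-crossing rate; respiratory-band
(0.1–0.6 Hz) power fraction; >1 Hz power fraction; spectral entropy;
dominant frequency.

DTW uses the classic unconstrained dynamic program with
absolute-difference local cost. Beats/breaths are cut to a fixed width
(±0.3 of the median period around each fiducial — wide enough for the
full P-QRS-T complex, narrow enough to exclude neighbours), resampled to
64 samples and z-normalized before comparison, so the distance is purely
morphological; beats whose span does not fit inside the window are
skipped. Fewer than three usable beats means the rhythm is
unassessable and the DTW statistics return a sentinel of 10.0 (far above
any clean adjacent-beat distance, per-sample scale). Spectral features
come from Welch periodograms (nperseg 512 ECG / 256 respiration);
spectral entropy is reported in nats, unnormalized.

The R-peak detector is a derivative–square–integrate chain with an
adaptive threshold (18% of the 99th percentile of the integrated energy)
and a 250 ms refractory period; detections are refined to the local
waveform extremum. The breath detector finds prominence-gated extrema
on a 0.4 s smoothed trace with a 1.5 s minimum period and enforces
peak/trough alternation. Both may legitimately return nothing on noise.

## Isolation forest

Written from scratch as the package's core. Growth contract: uniform
subsample of ψ rows per tree; at each node a split feature is drawn
uniformly among features that are non-constant in the node, then a split
value uniformly in that feature's open range; termination at height
ceil(log₂ ψ), at node size ≤ 1, or when no feature admits a split.
Scoring: s = 2^(−E[h]/c(ψ)) with exact harmonic numbers in c(n) up to
n = 1000 and the ln + γ approximation above. Defaults: 2000 trees
(matching the scale at which ensemble score noise is negligible —
two different forest seeds move scores by well under 0.02), ψ = 256,
contamination 0.05 stored as metadata only — grades come from the
calibrated thresholds, never from a native score offset. Features enter
raw: per-feature axis-parallel splits make the forest invariant to
monotone per-feature rescaling, so standardization would be cosmetic.
Models serialize to portable JSON (schema-versioned splits, sizes,
parameters, calibration), so scoring is reproducible across platforms.

## Threshold calibration

The candidate set for each threshold is the midpoints between adjacent
sorted unique scores plus one sentinel just outside each end of the
observed range (0.1% of the range beyond the extremes — every
decision-equivalent partition is visited exactly once, and a sentinel
can place all labels on one side). The pair maximizing overall accuracy
is returned; ties break by macro-F1, then smallest T2 − T1, then
smallest T1, making the search deterministic. The boundary convention
is half-open: a score exactly at T1 is acceptable, at T2 unacceptable.
The O(k²) accuracy surface is evaluated with class-count prefix sums,
so calibrating on thousands of labels takes milliseconds.

## Synthetic benchmark

The generator emulates the corruption taxonomy of wearable recordings:

* clean ECG: sum-of-Gaussians P-QRS-T template on a beat grid with
  fractional-SD period jitter; VPB = wide, large-amplitude,
  P-less complex on a premature (0.6 × period) slot with compensatory
  pause; APB = normal morphology, premature slot; rate modes at
  120/45 bpm for tachy/bradycardia.
* clean respiration: phase-integrated sinusoid with breath-wise period
  and amplitude jitter; apnea spans ramp to near-zero over 0.5 s.
* noise: baseline wander (band-limited random walk + slow sinusoid,
  0.05–0.4 Hz, scaled so the realized peak ratio to clean peak-to-peak
  equals the requested one), mains sinusoid, band-passed broadband EMG
  inside burst spans, 15 ms Gaussian impulses, and dropouts overwriting
  with the last held value.

Ground truth aggregates the realized components per window: wander
ratio, impulse count, dropout seconds, EMG seconds, unreadable-beat
count (beats whose local EMG+impulse RMS exceeds 0.5 × the clean beat
amplitude; beats inside dropouts are covered by the signal-loss clause
instead of being double-counted), and for respiration the regular
fraction — the part of the window outside apnea/dropout/EMG spans whose
breath period stays within ±25% of the record median.

The rule labeler returns the worst triggered clause. ECG: unacceptable
on dropout > 2 s, wander ratio ≥ 1, more than 2 impulses, or ≥ 2
unreadable beats; acceptable on any dropout, wander ≥ 1/3, any impulse,
one unreadable beat, or a non-trivial EMG burst; otherwise good.
Respiration: unacceptable on regular fraction < 0.25, wander ≥ 2, or
loss (apnea + dropout) ≥ half the window; good on regular fraction
> 0.75 with wander < 1; otherwise acceptable. Pathology annotations
never alter a grade. The labeler grades every window — there is no
analogue of annotators dropping windows they disagree on, which makes
the synthetic task slightly harder than a curated one.

Benchmark defaults are realistic monitoring mixtures: validation
87.3/5.5/7.2% (ECG) and 62.7/24.5/12.8% (respiration); the test split is
noisier, 80.4/6.1/13.6% and 67.5/17.6/14.9%. Split sizes (1200/1200/1000
windows ECG; 900/1200/800 respiration) keep a full run around a minute
while leaving ≥ 1000 validation labels for the label-efficiency
protocol. Each labeled window is generated by a per-grade noise recipe
that guarantees its rule label, so realized mixtures are multinomial
around the targets.

What passing on this benchmark shows: the pipeline recovers rule-derived
grades from waveforms alone, the score responds monotonically to noise
severity, and calibration is label-efficient. What it does not show:
performance on real recordings — real noise is correlated with posture
and activity, electrode artifacts are not additive Gaussians, real
pathology is richer than two ectopic templates, and annotator judgment
is fuzzier than any rule set.

## Alarms

The flaggers are simple documented rules over the beat segmentation:
bradycardia/tachycardia when the RR-derived rate stays beyond 50/100 bpm
for ≥ 10 s; a premature beat when an RR interval falls below 0.8 × the
local (7-beat) median, classified VPB if the beat is wide (> 60 ms at
half amplitude) or tall (> 1.3 × median), else APB. Alarm onset is the
beat instant. The audit counts an alarm false when its onset lies in a
poor-quality track interval; the default policy counts only
unacceptable intervals as poor, because acceptable signal still supports
rate analysis — a strict mode includes acceptable. Atrial
bigeminy/trigeminy flaggers are omitted: rhythm-pattern detection adds
nothing to the quality-assessment contribution.

## Known limitations

* The acceptable grade is intrinsically ambiguous; its recall is low
  (as it is for human annotators), and overall accuracy leans on the
  class imbalance.
* The generator's noise classes are additive and independent; real
  artifacts co-occur and interact with electrode mechanics.
* Heavy baseline wander is largely removed by the ECG band-pass before
  feature extraction, so wander-only acceptable windows are the hardest
  to separate from good ones — the synthetic recipes therefore mix
  wander with the defect classes that survive filtering.
* Thresholds transfer between splits only as far as the score
  distribution does; recalibration is advisable per device generation.
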