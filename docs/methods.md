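# Methods

## Detection model

The detector belongs to the waveform-analysis family: it transforms the ECG
into a *feature signal* in which QRS complexes dominate, thresholds it
adaptively, and localizes one R-peak per supra-threshold region.  The design
assumes (i) QRS energy concentrates in roughly the 5–15 Hz band, (ii) beats
are separated by at least a physiologic refractory interval, and (iii) on
multilead recordings a genuine beat appears near-simultaneously on most
leads while artifacts are usually lead-local — which is why majority
polling across leads is the default fusion rule.

Processing is batch, per segment.  Long records are split into 300 s
segments with 2 s overlap; detection cost is dominated by per-sample
filtering and squaring, so segmentation bounds memory and keeps the work
linear in record length.

## Pipeline and parameters

| stage | parameter | default | why |
|---|---|---|---|
| detrend | spline knot spacing | 1 s | tracks respiratory wander (≤ 0.5 Hz) without absorbing ST segments; knot value = window median, insensitive to QRS spikes |
| notch | mains frequency, harmonics | 50 Hz, 2 | configurable to 60 Hz; 1 Hz bandwidth; harmonics above Nyquist skipped |
| low-pass | cut-off | 25 Hz | removes EMG while leaving the 5–15 Hz QRS band intact |
| motion filter | window, ratio k | 0.2 s, 8 | flags local variance > k × median of the rolling 1 s maximum of local variance; flagged samples clipped at 2 × RMS of clean samples |
| PT band-pass | band | 5–15 Hz, Butterworth order 2 | integer-coefficient originals assume 200 Hz; an IIR designed at native fs works from 128 to 360 Hz |
| derivative | kernel | fs/8 · [1 2 0 −2 −1], centered | exact slope on ramps, zero delay |
| integration | window | 150 ms | canonical smoothing that turns QRS slope bursts into single humps |
| threshold | α, β, update | 3, 0.5, 3 s | α·mean + β·std per disjoint window; flat (all-zero) windows inherit the previous threshold so detection does not free-run when a lead drops out |
| region widening | 75 ms | each side | recovers QRS onsets/offsets clipped by the threshold crossing |
| fine search | window, "soft" signal | 100 ms, 40 Hz low-pass | the feature chain displaces maxima; the soft signal retains the true R apex |
| refractory | 250 ms | keep-larger greedy | above the maximum sinus rate; suppresses T-wave doubles |
| fusion | tolerance | 10 ms (min. 1 sample) | at 128 Hz, 10 ms is sub-sample, so the floor is 1 sample |
| matching | tolerance | 150 ms | the AAMI EC57 beat-matching convention |

All filters run forward–backward (zero phase).  On clean synthetic ECG the
full preprocessing chain shifts the R fiducial by at most 1 sample and
preserves its amplitude within 15 %.

### Notes on specific choices

* **Motion-artifact statistic.**  A naive comparison of local variance
  against the record median flags every QRS complex (the ECG is inherently
  spiky).  The reference used here is the median of the *rolling 1 s
  maximum* of local variance: on clean ECG every 1 s window contains a QRS,
  so the reference sits at QRS level and normal beats are never touched,
  while motion artifacts an order of magnitude larger are clipped.
  Clipping, rather than blanking, is used so the threshold statistics
  downstream see no dead zones.
* **Combinational product feature.**  The per-lead product
  `y[n,i] = x_f[n,i]·Π_{j≠i} x_f[n,j]` reduces algebraically to the full
  product over all leads for every `i`, so its per-lead columns coincide.
  It is implemented exactly in that form; users wanting genuinely per-lead
  decisions should use the per-lead PT pipeline with polling fusion
  (`"poll-input"`), which is the recommended configuration.
* **Matrix features and T waves.**  PCA/ICA features square a projection of
  the (low-passed) signal itself, not a derivative; prominent T waves can
  therefore cross the threshold and, being ~280 ms from the R apex, survive
  the 250 ms refractory.  This is an inherent weakness of the squared-
  projection family relative to the derivative-based family and is visible
  in their higher error rates; it is not "fixed" here by special-casing.
* **ICA component choice.**  Components are ranked by excess kurtosis; the
  QRS spike train is strongly super-Gaussian so the beat carrier ranks
  first.  Squaring the component removes ICA's sign ambiguity.  FastICA is
  seeded for determinism and falls back to the PCA feature (with a warning)
  on convergence failure.
* **Fusion semantics.**  Events from all leads are sorted and clustered:
  a cluster closes when the next event is more than the tolerance away
  from the cluster's first event; a cluster is emitted if it is supported
  by enough distinct leads (And: L, Poll: ⌊L/2⌋+1, SC: 2, Or: 1); the
  fused index is the cluster median.  For L = 2 a majority is 2, so Poll
  coincides with And; for L = 3 Poll and SC coincide.  With one lead every
  rule degenerates to the single list.
* **Segment stitching.**  Each interior segment reports only peaks at
  least half an overlap (1 s) away from its edges; the neighboring segment
  covers the trimmed band with full filter context.  This removes both
  boundary duplicates and filtfilt edge transients; remaining duplicates
  closer than the fusion tolerance are merged keeping the earlier index.
  On a clean 20-minute record, whole-record and segmented runs produce
  identical peak lists.
* **Threshold update windows** are disjoint, not sliding — a sliding
  update would cost an extra pass per sample for no measurable benefit at
  the 3 s scale.
* **Fine search placement** runs per lead *before* fusion, so each lead
  votes with its own best estimate of the R apex.

## Evaluation conventions

True negatives are counted as inter-beat intervals (gaps between
consecutive annotated R-waves) free of false positives: a record with R
annotated beats has R−1 decision opportunities for the negative class.
`B` in the accuracy and error formulas is `TP+FP+FN+TN`; this is the only
convention under which `Acc ≤ 100` and `Acc + Error = 100` hold
identically, and the test suite asserts that identity on every evaluation.
Matching is a sorted two-pointer greedy that attains maximum-cardinality
matching for points on a line; it is cross-checked against an optimal
assignment oracle on small instances.

Threshold tuning is a K-fold grid search over (α, β): each fold selects the
grid point minimizing pooled training error and is scored on the held-out
records; the returned point minimizes the mean held-out error.  When
several grid points tie (e.g. all reach zero error on clean data) the
first in grid order is returned.

Detector-vs-detector comparison classifies each reference beat as caught
by one detector only, by both, or by neither, and groups the
one-detector-only misses into bursts (runs of ≥ 3 consecutive beats) or
single beats — the categories used when auditing a commercial Holter
algorithm against this one.

## Synthetic data

The generator places a sum-of-Gaussians template (P, Q, R, S, T bumps at
fixed physiologic offsets; R amplitude 1 mV, width σ = 18 ms) at RR
intervals drawn from `60/HR · (1 + jitter·N(0,1))`, clipped at 300 ms.  R
centers are snapped to the sample grid before rendering, so annotations
are exact per construction.  Leads are positive scalings of one template
(default gains 1.0, 0.85, …) plus 5 µV RMS independent sensor noise per
electrode — real electrodes never produce mathematically identical
channels, and rank-deficient lead sets would make the matrix methods
ill-posed.

Noise generators: baseline wander (< 0.5 Hz filtered random walk),
powerline (mains sinusoid + harmonics), muscle (20 Hz–Nyquist band-passed
white noise), electrode motion (sparse smooth transients, ~0.2/s), and
per-lead disconnects (railed-flat spans).  Stationary types are
power-matched so the achieved SNR equals the request exactly.  The LTM
surrogate assigns a per-"day" muscle SNR profile, with the day length
compressible (60 s in tests) so week-long scenarios run in seconds.

What the generator does *not* emulate: ectopic morphologies (PVC runs,
atrial fibrillation), QRS-axis changes, electrode repositioning, or
recorded noise with realistic spectra.  Passing the synthetic suite
therefore demonstrates the pipeline's mechanics — localization, fusion
logic, scale invariance, segmentation equivalence, noise-floor robustness
— not clinical-grade performance; the latter is what the PhysioNet
benchmark runners in `ltmbeat.benchmarks` measure when the databases are
available locally.

## Problem sizes

The self-contained tests and the acceptance script use 20 s–20 min records
at 200 Hz with 2 leads, 100 randomized fusion configurations, and a 3×3
tuning grid over four 20 s records; the segmentation-equivalence check
uses a 20-minute record against 300 s segments.  These sizes exercise
every code path (multiple segments, multiple threshold windows, every
fusion rule) while keeping a full run under a minute.

## Known limitations

* Batch only; no streaming/real-time mode.
* WFDB support covers header+signal formats 16 and 212 and the MIT
  annotation stream — sufficient for the MIT-BIH family — not the full
  format zoo (no EDF/ISHNE).
* The specificity figure inherits the non-standard gap-based TN
  convention; it is not comparable to specificity in classification
  settings.
* Thresholds on heavily pathological rhythms (e.g. bigeminy with small
  ectopic beats) may need per-cohort re-tuning via `tune_threshold`.
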