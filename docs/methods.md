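# Methods

This note documents the models, defaults and numerical choices behind
`cardiogate`, and what the synthetic cohorts can and cannot establish
about real data.

## Heartbeat model

Inter-beat intervals (IBIs) are a stationary Gaussian AR(1) process:

    I_k − μ = φ (I_{k−1} − μ) + ε_k,   ε_k ~ N(0, σ² (1 − φ²))

so that the marginal SD of the IBIs equals `sdnn` (σ) for any lag-1
autocorrelation φ (`ar1`). The first IBI is drawn from the stationary
distribution. An optional additive sinusoid (`rsa_amp` ms at
`rsa_freq` Hz, evaluated at the nominal beat times k·μ) emulates
respiratory sinus arrhythmia. This is the simplest generative process
with independently tunable mean rate, SDNN and short-range
autocorrelation; it deliberately omits QRS morphology, ectopy,
artifacts and nonstationarity (drift, arousal responses), so gating
results on synthetic cohorts bound performance under *clean* ECG only.

Defaults: `mean_ibi` 850 ms (≈71 bpm, a typical resting young-adult
rate), `sdnn` 30 ms (mid-range resting short-term variability),
`ar1` 0, `rsa_amp` 0. IBIs below a 300 ms physiological floor are
clamped and the clamping rate is reported in the series metadata
(zero at the default operating point).

## Online R-wave handling

Detection is a threshold comparator: an event is the first sample at
or above the amplitude threshold in each upward excursion, subject to a
refractory period (250 ms default). This mirrors the fast-output
hardware the paradigm uses rather than a clinical QRS detector; there
is no artifact rejection.

The next R-wave is predicted from the three preceding event times as
t̂ = t₃ + mean(t₃ − t₂, t₂ − t₁) = t₃ + (t₃ − t₁)/2. Reading "three
preceding beats" as two IBIs averaged is the literal minimal
interpretation; `last` (one IBI), `linear` (IBI-trend extrapolation)
and `mean3` (three IBIs from four beats) are selectable alternatives.
Under i.i.d. Gaussian IBIs the default predictor's error SD is
σ·√(3/2) ≈ 36.7 ms at σ = 30 ms, which the offline
`prediction_error_profile` reproduces.

## Closed-loop gating

Each trial counts `min_beats_between_trials` (default 4) beats
occurring strictly after the previous trial's stimulus onset — the
variable inter-trial interval — predicts the next R-wave from the last
three of them, and schedules the onset at the phase offset (300 ms for
systole, 500 ms for diastole, after the *predicted* R-wave). The
detection latency (default 1 ms, hardware bound < 2 ms) delays only the
scheduling moment; event timestamps are the true R-peak times. The
trial's recorded latency is onset minus the nearest *preceding actual*
R-wave, even when an unexpected early beat intervenes — that is what
makes a-posteriori recoding meaningful. Whether the original rig
re-predicted when an early beat arrived before the scheduled onset is
unknown; this implementation does not, and such trials simply recode by
their actual latency.

## Phase recoding

Fixed windows partition latency: systole [200, 400] ms, diastole
[450, 800] ms, everything else excluded. The window definitions carry
no boundary convention in the source literature; here both endpoints
belong to their target window, which maximizes retained trials and can
only matter on a measure-zero set of integer latencies (the windows are
configurable). Exclusion rates are reported per subject and pooled; the
<10.5% reference bound is read as a pooled per-study ceiling. At the
default operating point (SDNN 30 ms) the pooled rate is ≈4.4%, driven
almost entirely by diastole-intended trials whose latency falls in the
ambiguous (400, 450) ms band.

## Behaviour model

Responses are Bernoulli in a per-cell probability map
(prime × object × phase). Correctness is keyed on the trial's *actual*
(recoded) phase, falling back to the intended phase for excluded-window
trials: the modelled physiological effect follows the heart, not the
scheduler. Response latency is lognormal, parameterized by its mean
(400 ms) and SD (55 ms); responses slower than the collection window
and outright misses (`miss_rate`, default 0.02) are recorded as no
response; responses between the deadline and the collection window are
kept for latency analyses but count as not on time. Misses and late
responses deflate all cells uniformly, so they shift accuracy levels
without creating spurious interactions.

The default accuracy maps are chosen once to reproduce each task's
qualitative pattern at effect sizes in the range the paradigm reports:

- WIT: systole cells 0.90/0.78/0.80/0.90 (black-weapon / black-tool /
  white-weapon / white-tool), diastole flat at 0.85. With 33 trials per
  cell this yields systole prime contrasts of d ≈ 1 and a three-way
  interaction F ≈ 30–40 at n = 30.
- FPST: armed cells at a 0.92 ceiling everywhere; unarmed cells
  0.80/0.86 (black/white) at systole, 0.84/0.83 at diastole — a smaller
  unarmed-only race effect (d ≈ 0.5).
- SFIT: a phase-invariant prime × object pattern
  (0.88 congruent / 0.84 incongruent at both phases).

The generator draws cells independently per subject with no
between-subject heterogeneity in the probabilities; subject-level
variance in cell accuracy is therefore purely binomial. Real cohorts
have wider between-subject spread, so power figures obtained from these
defaults are upper bounds for equal nominal effect sizes, and the null
calibration (below) checks validity, not realism.

## Statistics

The repeated-measures ANOVA decomposes sums of squares by
inclusion–exclusion over marginal means; every within-subject effect is
tested against its own subject × effect interaction with
df = (n − 1)·df_effect, and partial η² = SS_effect/(SS_effect +
SS_error). All factors here have two levels, so sphericity holds
trivially and no correction is applied, and each F equals the squared
paired t of the corresponding difference contrast (verified to 1e-9 in
tests). Accuracy enters untransformed (no arcsine), matching standard
practice for these tasks.

SDT indices use the standard normal quantile transform with a 1/(2N)
extreme-rate correction by default (log-linear selectable); which
correction the original analyses used is not stated anywhere, and at
33 trials per cell the choice moves d′ by < 0.1. d′/C are computed per
prime × phase, collapsing object into signal/noise roles. Hit and
false-alarm rates are the on-time accuracy of the signal cell and one
minus the on-time accuracy of the noise cell respectively, so the SDT
table is arithmetically consistent with the accuracy table.

Newman–Keuls runs the stepwise studentized-range procedure over
rank-ordered condition means; a comparison contained in a
non-significant wider range inherits that range's p (implemented as a
max over containing ranges, which also guarantees corrected p ≥ raw p).
The error term is the pooled within-subject mean square of the one-way
repeated-measures ANOVA over the means entering the comparison, with
df = (n − 1)(k − 1) — the source analyses do not specify theirs. For
k = 2 the procedure reduces exactly to the paired t-test (q = t√2).

Degenerate inputs are flagged, never silently imputed: an all-zero
difference vector gives t = 0, p = 1; a constant non-zero difference
gives an infinite t with a warning; PDP-automatic is NaN when
control = 1, and subjects with undefined values are dropped (and
logged) from that ANOVA only; empty accuracy cells are NaN, and a
subject missing a cell aborts the ANOVA with the subject listed.

## Problem sizes and calibration

The validation suite runs the full closed loop at study scale (30
subjects × 264 trials) for timing quantities, and uses the exact
marginal distribution of per-cell accuracy under ideal gating —
Binomial(n_trials, p)/n_trials — for the large-replicate calibration
studies (2000 replicates for the null rejection rate of the three-way
interaction, 200 for power patterns), since at those replicate counts
the heartbeat stream contributes nothing to the accuracy marginals.
Process-dissociation recovery is checked against a direct simulation of
the underlying process model (respond via control with probability c,
otherwise express the automatic bias a), which the estimator inverts
exactly in expectation.

## Known limitations

- Event times only: no continuous ECG morphology, no detector
  validation against real recordings.
- The fixed 200–400 ms systolic window is a population-level proxy; no
  subject-specific (e.g. QT-based) window adjustment is provided.
- No trial-level response-time analyses or mixed-effects models; the
  inferential layer reproduces the cell-means ANOVA workflow.
- FPST stimulus-identity structure (repeated pictures) is not
  modelled; the generator treats trials as exchangeable within cells.
  The FPST trial total follows from 23 trials per cell (184).
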