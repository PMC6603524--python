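# Methods

This note documents the models, estimators and design choices behind
`tremornet`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic benchmarks
do and do not establish.

## Signal conditioning

LFP channels are downsampled to 125 Hz (polyphase resampling with a
rational approximation of the rate ratio, so arbitrary clinical rates are
covered; upsampling is refused) and band-pass filtered to 2–45 Hz with a
single-pass 500th-order Hamming-window FIR. Two seconds of the recording's
own reflected edge data serve as filter warm-up and are trimmed afterwards;
the output is shifted by the filter's group delay (order/2 samples) so
window timestamps stay aligned with the input. The band excludes movement
artefacts (~1 Hz) and 50 Hz line noise by construction, so no notch filter
is applied.

EMG channels are processed at their native rate: a zero-phase (two-pass)
30 Hz high-pass of the same order, rectification by the magnitude of the
analytic signal (the series is reflect-padded before the FFT-based Hilbert
transform, which otherwise spikes at the edges), then the same 2–45 Hz FIR.
Tremor onset is declared at the earliest sample whose amplitude exceeds
3 × the mean over the first 5 s (assumed atremorous) *and* whose following
5 s also exceed that threshold on average; the confirmation window must fit
inside the recording, so a crossing in the final 5 s cannot be confirmed.
Threshold comparisons are strict (>).

Analysis windows are 2 s with 90% overlap (250 samples, hop 25 at 125 Hz);
each window's measures are assigned to its mid-point.

## Delay embedding

The delay τ is the first local minimum of the auto-mutual information,
estimated with an equal-width histogram of B = max(8, ⌊N^(1/3)⌋) bins
(natural logarithm; MI(0) equals the plug-in entropy of the binned
marginal). Equal-occupancy binning is available as an option but is not the
default: the rank transform it applies flattens the geometry of the lagged
return map, and on a noiseless oscillation the first-local-minimum rule
then fails to find the quarter-period lag at all. The local-minimum rule
allows a tie on the left and requires a strict rise on the right; if the
curve has no interior minimum, τ falls back to the first lag below MI(0)/e
(else the largest lag) with a warning. Note that a noiseless *integer*-
period oscillation has only P distinct amplitudes and is informationally
degenerate for any binned estimator; the test signals use incommensurate
periods.

The dimension m is the smallest with a false-nearest-neighbour fraction
≤ 1% (configurable), with the Kennel criteria R_tol = 10 and A_tol = 2 in
the Euclidean norm, a loneliness guard that excludes points whose nearest
neighbour is farther than one standard deviation of the series, and a
floating-point guard that never counts a pair separated only by numerical
noise (< 1e−8 σ) as false. On band-limited noisy signals the fraction
typically never reaches 1% and m saturates at m_max (default 10) with a
warning — the expected behaviour for noise-dominated data.

Both parameters are selected once per recording from its leading atremorous
data and held fixed across windows, so all windows yield networks of the
same size; a robustness sweep over m (see below) checks that this choice is
not critical.

## Recurrence networks and measures

Within each window the embedded states are compared in the maximum norm.
Instead of a fixed ε, the recurrence rate is fixed at RR = 0.03: ε is the
smallest pairwise distance whose cumulative fraction reaches RR
(deterministic non-strict quantile; ties can push the achieved rate off by
more than ±0.005, which is flagged). The boundary counts as recurrent
(Θ(0) = 1), the diagonal is removed, and no Theiler window is applied by
default (one is available). Degenerate windows — constant signal, all
states identical — yield missing values rather than aborting the time
course.

Global clustering averages the local closure C_i over *all* N vertices;
vertices with degree < 2 contribute C_i = 0. Transitivity is
3 × triangles / connected triples (0 when there are no triples).
Assortativity is the Pearson correlation of endpoint degrees over both
orientations of every edge; it is undefined (NaN, flagged) when the
endpoint degrees have zero variance, as on regular graphs. All three are
computed with dense matrix algebra and are tested to 1e−12 against naive
enumeration and against networkx.

## Significance bands and peaks

Each measure's time course is smoothed with a centred 21-window moving
median (≈ 4.2 s at the default hop; the half-window shrinks at the series
ends rather than padding). The subject's baseline is the initial stretch of
windows known or assumed atremorous — the leading NT-labelled windows when
labels exist, otherwise the first 5 s. The band **center** is the median of
the raw measure over that baseline and **σ** is, by default, the standard
deviation of the raw baseline values; an alternative mode uses only the
residuals from the median track. The total-spread default is deliberate:
the residual spread captures only the fast component of the baseline
variability, and thresholds built from it are crossed constantly by the
measure's slow wander.

Significance thresholds are *horizontal*: center + 2σ (labelled p < 0.05
under a Gaussian reading of the baseline spread) and center + 3σ
(p < 0.01); these labels are nomenclature, not a formal test, and no
multiple-testing correction across windows is applied. The tested statistic
is the trigger-memory average (current window + 4 predecessors) of the
*median-filtered* signal; judging transients on the smoothed signal is what
makes single-window spikes insignificant. A raw-statistic mode exists. For
each level, every maximal run above the threshold emits one event at its
first window, so a sustained step produces exactly one 3σ onset event.

## Closed-loop controller

While stimulation is off, the controller holds the last four windows in a
FIFO memory, averages them with the current window and issues START when
the average exceeds center + 2σ of the clustering measure (the measure with
the most abrupt pre-tremor peaks; configurable). The trigger is armed only
once its memory is full — a freshly started (or re-armed) controller first
gathers its four-window context. While stimulation is on, a per-patient
classifier labels each window from its raw (C, T, A) features and STOP is
issued at the first NT label; STOP clears the trigger memory so the re-armed
trigger is not contaminated by tremor-era values. The controller consumes
the same median-filtered measure series whose transients the significance
analysis judges.

The stop classifier is an RBF SVC (class-balanced, default C and gamma)
on standardised per-window features — (C, T, A) and their four-window
means, with missing assortativity imputed by the column median. Validity is
reported from a pooled confusion matrix over ten-fold stratified
cross-validation (seeded); sensitivity/specificity follow the positive
class: T for the stop task, NT for the harder NT-vs-TO onset task, and
FPR = 100 − specificity, FNR = 100 − sensitivity hold exactly by
construction. Because adjacent windows share 90% of their samples, plain
stratified folds leak information; a contiguous-block CV mode is provided
for leakage-free estimates, with the stratified variant as the default
protocol.

## Synthetic data

The generator encodes the dynamical premise the method tests — nothing
more. NT activity is Gaussian noise band-limited to 10–30 Hz by a 300-tap
FIR (a plain second-order autoregression cannot realise this band at
1000 Hz: a moderate pole radius leaks most power below 8 Hz, a near-unit
radius degenerates into a quasi-sinusoid whose windows mimic
low-dimensional structure). T activity mixes in the x-component of a
Rössler system (a = b = 0.2, c = 5.7; fixed-step RK4, 50 time units of
transient discarded, time rescaled so the dominant frequency equals the
5 Hz tremor frequency) with weight 0.8 and amplitude gain 2. The TO
transition follows a sigmoid ramp over its 10 s; tremor offset is abrupt.
White measurement noise is added at 10 dB SNR. The EMG is a 35–150 Hz
noise carrier amplitude-modulated by tremor-phase-locked bursts (gain 4)
that start midway through TO and stop at the end of T, so the LFP
nonlinearity rise precedes the symptom — the margin the closed loop
exploits. Default durations are 15/10/15/10 s (NT/TO/T/trailing NT),
50 s in total, within the range of the clinical recordings the protocol
targets; the trailing atremorous segment is what allows a STOP decision to
be exercised at all. All draws flow from one seeded generator;
fixed seed ⇒ bit-identical output.

What the synthetic benchmarks show: that the implementation detects a
*constructed* nonlinearity increase before a *constructed* tremor boundary,
with controlled false-peak behaviour under a matched linear null. What they
do not show: that real subthalamic dynamics follow this generative model,
that the 10 dB SNR or the sigmoid ramp is physiological, or how the
classifier transfers across patients.

## Problem sizes and numerical choices

Monte-Carlo suites use 100 seeded recordings per condition (40-s nulls,
50-s tremor scenarios); graph-measure oracle checks use 200 random graphs
with N ≤ 50; benchmark signals use 2000–10000 samples. A full analysis of
one 50-s recording (conditioning, parameter selection, 241 windows of
network construction and measures, bands, peaks, control loop) takes well
under two seconds on one CPU core. Ties in the ε-quantile are resolved
downward deterministically; all warnings (degenerate windows, selection
fallbacks, tie drift) are real `warnings` categories so batch runs can
filter or escalate them.

## Known limitations

- The embedding-dimension rule saturates at m_max on realistic noisy
  signals; the measures are robust to this (the m-sweep correlation is the
  evidence) but m itself is then not meaningful.
- The 2σ/3σ ↔ p-value correspondence assumes Gaussian baseline residuals.
- The oracle (label-reading) stop classifier used in closed-loop tests
  stops at the labelled boundary, slightly before the band-pass filter's
  smearing of the tremor offset has decayed; in a small fraction of runs
  the re-armed trigger then fires once more. A trained classifier, which
  reads features rather than labels, does not share this artefact.
- EDF export is not implemented (reading is, via mne); all writers emit
  tab-separated text.
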