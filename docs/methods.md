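# Methods

This note records the modeling choices behind `serj`: what the pipeline
computes, what the synthetic-data generator does and does not emulate, the
defaults that matter, and the places where the design was genuinely open.

## Signal conditioning

**EDA.** Raw device counts may carry a hardware bias; the de-biasing
transform `f = r − ((a + b·r)·c)/(d − r)` with device constants a=2014, b=2,
c=10000, d=512 is implemented behind `mode="divide"` and is **off by
default**: the constants are specific to one acquisition device, and any
signal not coming off that device's raw serial counts (including all
synthetic data) must pass through untouched.  A sample equal to d sits on the
transform's pole and raises a singularity error naming the index.  Denoising
is 3-level discrete-wavelet shrinkage (db4, soft universal threshold with the
noise scale from the finest detail band's MAD).  All defaults are
configurable.

**PPG.** Zero-phase (forward–backward) digital Butterworth low-pass, order 4,
cut-off 10 Hz.  The analogue magnitude form `H(D) = 1/(1+(D/D0)^{2n})` is
exposed as a closed form (`butterworth_magnitude`); it is 1/2 at D = D0 and
flat in the pass band, which the tests verify on the digital realisation
(DC gain within 1 %, monotone non-increasing gain over a frequency grid).

**Scaling.** Both channels are min–max scaled to 0–100 **per whole trace**,
not per 10-s segment.  Per-segment scaling would pin every window's range at
exactly 100 and erase precisely the amplitude contrast the decision rules
gate on; per-trace scaling is a positive affine map, to which all judgments
are invariant (their normalization happens per feature stream).  A constant
segment is reported as degenerate rather than silently zeroed.

## Windowing

Calculation segments are non-overlapping half-open 10-s windows; a trailing
partial window is dropped so every window has identical sample count.
Min/max ties resolve to the first occurrence; indices are 0-based.  These
conventions make `n_max` vs `n_min` comparisons deterministic.

## Features

The three named optimal features are `bpnn50` (strict `|Δ| > 50 ms` on
successive main-wave inter-beat intervals, divided by N−1; a signed-difference
variant is available by configuration), `eda_range`, and `eda_1dmean`
(signed; telescopes to `(x_N − x_1)/(N−1)`, which the tests exploit as an
independent oracle).  Inter-beat intervals are measured between main-wave
peaks, and a window's BpNN50 uses only intervals whose two bounding peaks lie
inside it, so state transitions at window boundaries cannot leak in.

Main-wave peaks are found by prominence-based peak picking (floor at 30 % of
the local robust amplitude span) on overlapping 10-s chunks, with the span
computed on linearly detrended samples so that slow baseline drift cannot
mask low-amplitude beats, and chunk-local thresholds so that amplitude
changes across a recording do not mask quiet stretches.  Within a beat, the
dicrotic notch is the first local minimum after the main peak, the dicrotic
wave the first local maximum after the notch (within 60 % of the period), and
the dicrotic anterior wave the point of maximum curvature on the descent —
the "shoulder".  The waveform onset is the foot preceding the main peak.
Beats without a successor peak are not delineated.

The full catalog holds 24 EDA and 18 pulse time-domain descriptors, six
frequency-domain descriptors per channel computed by one shared periodogram
implementation (total power, three band powers at 0–0.5/0.5–2/2–5 Hz,
spectral centroid, spectral entropy), seven EDA physiological descriptors
(SCR-like phasic events over a moving-minimum tonic estimate) and ten pulse
physiological descriptors (beat timing statistics including BpNN50, fiducial
amplitudes and ratios).  Windows with fewer than three beats report pulse
physiological features as **absent, never zero**; constant windows likewise.

## Optimal-feature selection

Stage 1 standardizes the table and runs PCA, retaining components up to a
90 % explained-variance target.  A feature's weight in the retained
components is its **communality** `Σ_k λ_k · loading²` — the fraction of its
variance the retained subspace explains.  Features above an absolute weight
threshold of 0.5 (majority of variance explained) survive; a mean-weight rule
is available.  Two alternatives were considered and rejected after
measurement: scoring by the largest absolute loading punishes exactly the
informative features (a block of collinear label-driven descriptors splits
its shared direction's loading among its members), and an 85 % variance
target often truncates the third structure component of the quadrant code
(the EDA trend-sign contrast separating HANV from LAPV), since few
descriptors carry it.  The quadrant code spans three independent contrasts —
arousal level, EDA amplitude level, EDA trend sign — so the retained subspace
must hold at least three structure components.

Stage 2 computes Pearson r and two-sided P between each surviving feature
and a one-vs-rest indicator per quadrant (ordinal coding of quadrants would
impose an arbitrary metric on a categorical plane); a feature is kept for a
quadrant when |r| ≥ 0.3 and P < 0.05, and the final subset is the union over
quadrants.  On default benchmark sessions this recovers
{`bpnn50`, `eda_range`, `eda_1dmean`}, with `eda_range` correlated with both
LAPV and HANV — the two quadrants whose signature it is.

## The judge

`x_th` is the mean of the min–max-normalized **feature stream across
windows** (not raw samples): thresholds must live on the scale of the values
they gate.  Normalization parameters and `x_th` freeze after a calibration
prefix (default four windows, emitted as UNDECIDED) and later values clip
into [0, 1]; freezing keeps decisions causal and reproducible, and a rolling
mode can be added without changing the decision contract.  All comparisons
are strict, so boundary equality falls to the "otherwise" arm.  When both
branches fire, priority HANV > LANV > LAPV > HAPV resolves the conflict:
negative-valence states drive the adaptation policy, and HAPV triggers
nothing.  Every decision records a rule trace (test name, operands, outcome)
sufficient to replay it.

An important property of this scheme: a feature stream only discriminates
when its calibration span exhibits contrast.  If all calibration values sit
at one level, the frozen band is noise-wide and same-level values later fall
on either side of `x_th` at chance.  The generator's default benchmark cycle
(below) is ordered so the calibration prefix spans both levels of every gated
feature.

## The synthetic generator

The generator emulates the statistical structure the rules test, one
canonical signature per quadrant:

| quadrant | EDA range | EDA trend | EDA slope | IBI jitter | pulse range | pulse slope |
|---|---|---|---|---|---|---|
| HANV | high | rising | high | low | low | low |
| LAPV | high | falling | high | low | low | low |
| LANV | low | rising | low | high | high | low |
| HAPV | low | rising | low | high | low | high |

EDA windows are smooth ramps (amplitude 8 high / 1 low, arbitrary units on a
tonic baseline of 5; a "low slope" ramp rises and settles back to a quarter of
its amplitude, so range and net displacement decouple).  PPG is a train of
per-beat templates — three Gaussian components forming the main wave, a
dicrotic anterior shoulder and the dicrotic wave with a notch between them —
placed at beats whose intervals alternate `base ± jitter` around a base of
10/12 s (72 bpm).  The alternation is a stylised respiratory sinus
arrhythmia: its standard deviation equals the nominal jitter, and every
successive-interval difference has magnitude 2·jitter, pinning per-window
BpNN50 at 0 (jitter 10 ms) or 1 (jitter 80 ms).  Twelve beats fit one window
exactly, so windows are beat-phase-aligned and boundary effects cancel.
Pulse "slope" is a baseline drift (1.5 units per window) that relaxes
exponentially (τ = 2 s) across segment changes — an instantaneous step would
be smeared backwards by the zero-phase filter into the preceding window's
`1dmean`, and perfusion baselines do not step instantaneously anyway.
Additive Gaussian noise at 2 % of the channel span rides on both channels.
Everything derives from one seed and is bit-identical under it.

The default benchmark session is one LANV→HANV→LAPV→HAPV cycle, three
windows per segment.  The order matters: the four calibration windows are
then 3×LANV + 1×HANV, which jointly exhibit both levels of EDA range, EDA
1dmean, BpNN50 and pulse range (pulse 1dmean is one-sided in calibration but
is only ever consulted for windows that already passed the BpNN50 gate and
failed the pulse-range gate, whose drifted values clip to 1).

Per-subject variability redraws the level parameters (EDA amplitudes and
baseline, pulse amplitudes and drift) within ranges chosen so the
per-quadrant contrasts survive every draw — in particular the drift stays
below 0.75× the worst-case pulse amplitude contrast, so a drifting
low-amplitude pulse never mimics a high-amplitude one — and applies a random
positive affine transform per channel.  The affine part is invisible to the
judge by construction; the level redraws shift the feature geometry a
classifier trained on another subject must absorb.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: physiologically calibrated SCR kinetics and
habituation, motion artifacts, sensor dropout, heart-rate nonstationarity
beyond the alternating jitter, realistic (much noisier) pNN50 distributions,
and any coupling between channels.  Real BpNN50 values in particular are
binomially noisy at ~12 intervals per window; the generator's near-binary
values isolate the rule logic from that sampling noise by design.

## Baseline and comparison

The baseline is an SVM (RBF kernel, C = 1, gamma = "scale" — the comparison,
not the tuning, is the point) over the full catalog with mean imputation and
standardization, fitted on a stratified, seeded 70 % split; classes with
fewer than 10 windows are refused.  The cross-subject benchmark trains on one
synthetic subject and evaluates both approaches on the post-calibration
windows of another (both protocols — within- and cross-subject — are
exposed; cross-subject is the benchmark default, since the judge is the one
with a per-subject calibration mechanism).

Activation counting: an event counts as an activation only when its
triggering decision matches the window's ground-truth quadrant.  Raw event
counts would reward a *wrong* classifier — an isolated misclassification
breaks a run and retriggers after the refractory period, inflating events —
whereas an event fired on a misjudged window does not activate the subject's
actual emotion.  Raw totals are reported alongside.

## Adaptation policy

Fixed mapping HANV → reward bricks, LAPV → spawn monsters, LANV → new scene,
HAPV → no action.  An event fires when a quadrant persists for k consecutive
windows (default 1) and is then refractory for r windows (default 1);
UNDECIDED resets persistence.  HAPV is logged per window but never fires, so
activation tables can represent its column as empty (NA), distinct from 0.
The second new-scene event marks the session context ended (configurable),
matching the reference account of a subject who left the game after two
scene changes.  With k = 1, r = 0 the event stream is exactly the decision
stream minus HAPV/UNDECIDED, which the tests assert.

## Numerical conventions and degenerate inputs

Strict inequalities throughout the rule tree; first-occurrence tie-breaks in
extrema; 0-based window and sample indices; constant reference spans raise
degenerate-threshold errors rather than producing NaNs; absent pulse features
make a decision "partial" (EDA branch only) rather than failing the session.
Thresholds, filter order, wavelet family/levels, calibration length,
persistence and refractory are all configuration with the defaults above.

## Problem sizes

The packaged benchmarks use 12-window (120 s) sessions for parameter
recovery and feature-set recovery (20 replicates) and 60-window (600 s)
sessions for the cross-subject comparison (3 subject pairs in the acceptance
script); these sizes give stable statistics for every quantity reported
while keeping a full run in seconds.
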