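# Methods

This note documents the models, estimators, and numerical choices behind
`betawheel`, and what the synthetic-data tests do and do not establish about
real recordings.

## The paradigm and the synthetic cohort

The task emulated by the generator is continuous wheel turning with cued
starts, direction reversals, and stops, in two conditions. In the
*predictable* condition every trial is start → reverse after 4 s → stop
after another 4 s, followed by a 4 s pause, with 36 trials per block and two
blocks per condition. In the *unpredictable* condition each trial contains
0, 1, or 2 reversals with equal probability, and inter-stimulus intervals
are a mixture: with probability 0.5 the interval is held at 4 s, otherwise
it is drawn uniformly from 4–7 s. A permutation test on the lag-1
autocorrelation of the generated intervals confirms they carry no serial
structure beyond the mixture.

A single sample rate of 500 Hz is used for the encoder trace and all neural
channels; the analysis operates post-downsampling, so nothing is gained by
simulating a faster encoder clock and resampling.

### Kinematics

Each cue draws a reaction time from a normal distribution truncated at
0.05 s (and below the next inter-stimulus interval), with condition- and
event-specific means and SDs. The start/stop defaults are the group values
of the paradigm (start: 0.757 ± 0.154 s predictable, 0.840 ± 0.160 s
unpredictable; stop: 0.824 ± 0.202 s and 0.889 ± 0.233 s). Reversal
reaction times are not reported anywhere for this task; the defaults
(0.80 ± 0.18 s and 0.86 ± 0.19 s) were chosen once, in the same range as the
printed start/stop values.

The speed profile ramps linearly to ±400 deg/s in 0.25 s; a reversal passes
through zero with a 0.1 s standstill centered on the ground-truth reversal
event; a stop decays to zero at the ground-truth stop event. Ground truth
is defined as movement onset (start), the turning-point midpoint (reversal),
and the final halt (stop), all at cue + reaction time. Speed noise
(8 deg/s RMS, low-passed at 3 Hz) is applied only while the hand moves — a
still finger produces no encoder jitter beyond quantization — and the angle
trace is quantized at 0.1°.

### Neural signals

Each channel is a 1/f^1.5 background (one-sided PSD 0.004 units²/Hz at
20 Hz) plus band-limited oscillations modeled as white-noise-driven damped
resonators (AR(2); beta at 20 Hz with pole radius 0.97, gamma at 65 Hz with
radius 0.95). The resonator was chosen because no generative model is
implied by the analysis itself and AR(2) gives direct control over center
frequency and bandwidth with an analytic PSD — which the recovery oracles
exploit.

Event-locked gains multiply the oscillation amplitude envelope (raised-
cosine edges, 0.1 s): beta suppression −3 dB at start (bilateral), beta
rebound +2.5 dB contralateral / +1.0 dB ipsilateral after stop, brief
reversal modulations (−1 dB cortex, +1 dB contralateral STN), and a +1.5 dB
contralateral STN gamma increase at start. These depths are free generator
parameters — the paradigm's publications print no dB values — and every
recovery test compares estimates against the *configured* truth, never
against published group numbers.

Directed coupling adds a strictly lagged (≥1 sample), scaled copy of the
source's band component to the target (cortex → STN beta, 20–24 ms lags),
optionally gated by event- and condition-dependent gains (stronger
event-locked coupling in the unpredictable condition). This makes directed
influence source → target by construction and gives the coherence a
closed-form value, coh = c·S_osc / √(S_xx · S_yy), used as an oracle.

Subjects get independent random streams spawned from one seed
(`numpy.random.SeedSequence`); identical seeds reproduce cohorts bitwise.
Channels are labelled by physical side (left/right); contralateral/
ipsilateral roles are re-derived from each subject's moving hand.

### What the generator does not emulate

No volume conduction or sensor-space mixing, no tremor or artifacts, no
1/f knee or nonstationary background, no trial-to-trial kinematic-neural
correlation beyond the event envelopes, and no between-subject heterogeneity
in modulation depths. Passing tests therefore establish the correctness and
calibration of the estimators under the stated generative model — not
robustness to real-recording pathologies such as artifacts, non-Gaussian
noise, or head movement.

## Event detection

The wheel speed is the central difference of the angle trace, smoothed with
a 50 ms moving average (enough to suppress quantization noise without
blurring reversals). Detection is cue-windowed: each cue opens a search
window up to the next cue. A start requires |speed| above 50 deg/s
continuously for 0.3 s; the threshold crossing is back-projected to movement
onset by walking to a 10 deg/s floor, which removes the ramp-dependent bias
of raw threshold crossings. A stop is the first sustained sub-threshold
run, projected forward to standstill. A reversal is a zero crossing flanked
within 0.5 s by supra-threshold speed of opposite signs; the event is the
midpoint of the sub-floor standstill. Events violating the cue ordering are
dropped with a logged reason — a deterministic stand-in for manual
correction. At the default noise level this yields sensitivity 1.0 and a
mean absolute timing error under 5 ms (95th percentile under 20 ms).

Time convention throughout: seconds relative to the event (event at 0),
0-based sample indices, half-open windows [t0, t1).

## Multitaper spectra

Epochs span ±2 s. The sliding-window transform uses 800 ms windows stepped
by 50 ms over −1.6–1.6 s (bins whose window would leave the epoch are not
computed; no padding). Two bands are analyzed separately: 5–45 Hz with 4
Slepian tapers and 55–90 Hz with 7 (the gap skips 50 Hz line noise). With
K = 2NW − 1 the half-bandwidths are 3.125 and 5 Hz. The frequency grid is
the Rayleigh spacing of the window, 1.25 Hz — the window length and taper
counts are fixed by the paradigm's analysis, the grid is this package's
choice. Power is one-sided spectral density (2|X|²/fs with unit-energy
tapers), so integrated power equals tapered-signal variance (Parseval,
tested to 1%). Coherence pools trials × tapers as observations; its
small-sample bias (mean coherence² ≈ 1/N under independence) is verified
against simulation.

Baseline correction uses the per-frequency mean over −1.6–0 s: decibel for
power, subtraction for coherence. Band summaries average the corrected map
over 13–30 Hz (beta; 13–20/20–30 for low/high beta) or 55–90 Hz (gamma) and
over the pre (−1.6–0 s) and post (0–1.6 s) windows; channel/ROI selection
and Granger use whole-segment spectra over ±2 s windows instead of the
sliding transform.

### Truth propagation

A sliding-window estimate of a time-limited modulation is diluted by windows
straddling its edges, and the measured dB change also mixes in the 1/f
background. Recovery tests therefore compare estimates against an expected
value propagated from the configuration: oscillator and background PSDs are
evaluated analytically, each TFR bin's oscillation power is scaled by the
mean squared envelope over that window — weighted by the mean squared taper
profile, since tapers weight the window center more than its edges — and the
same baseline/band-averaging arithmetic is applied. Taper smoothing in
frequency is neglected, which is accurate for band averages much wider than
the taper bandwidth. The analogous coherence oracle integrates the analytic
cross- and auto-spectra over the taper concentration band, including the
phase rotation of the coupling lag.

## Nonparametric Granger causality

Cross-spectra of the post-event 0–2 s window use ±4 Hz multitaper smoothing
(15 tapers at 2 s) — the window is fixed by the analysis design, the
smoothing is this package's choice for stable factorization at ~60 trials.
Wilson's iterative spectral matrix factorization computes
S(f) = H(f) Σ H(f)ᴴ with minimum-phase H and H(0) = I, iterating
ψ ← ψ·{ψ⁻¹Sψ⁻ᴴ + I}₊ on the full frequency circle. The causal-part
operator keeps non-negative lags, splits the zero-lag matrix as half its
diagonal plus its strict upper triangle, and — a detail that matters —
halves the lag-nfft/2 component, which is shared between the causal and
anticausal parts; without this the iteration plateaus near 3×10⁻⁵ relative
residual instead of converging below 10⁻⁸. Tolerance 10⁻⁸, at most 100
iterations, diagonal loading 10⁻¹⁰·trace on near-singular input;
non-convergence raises with the residual attached. The factorization and
the Geweke spectrum are validated against a closed-form bivariate VAR(2)
cross-spectrum (innovation covariance to <2%, directed spectrum to <5% of
the parametric value).

Every contrast is recomputed on time-reversed trials. Both the raw
directional estimates and the delta are emitted, since analyses may use
either as the dependent variable. Band averages use the same 13–30 and
55–90 Hz bands as power.

## Cluster-based permutation test

Group inference over (frequency × time) bins: one-sample t across subjects,
cluster-forming threshold at the two-sided 0.05 critical value (df = N−1),
clusters connected under 4-neighbor adjacency (the conservative, simplest
choice; 8-neighbor is available), cluster mass = sum of t. The null is the
permutation distribution of the per-sign maximum mass under random
per-subject sign flips (sum of squares is sign-invariant, so permuted t maps
are computed from flipped means alone). The two-sided cluster alpha 0.05 is
split as 0.025 per tail, the observed statistic is included in the null
(p ≥ 1/(n_perm+1)), and subjects — not trials — are the permutation unit,
matching group-average inference. Calibration: on null cohorts the
family-wise error is at the nominal 0.05 (checked over 200 cohorts). With
few trials per subject the decibel maps carry a small common log bias
(E[ln χ²_k/k] < 0) shared across subjects, which can tilt the negative tail;
the calibration suite therefore runs at the paradigm's ~60 trials per event,
where the bias (≈ −0.01 dB) is well below the between-subject noise floor.
On ideal Gaussian null stacks the test is exact (measured 0.057 ± 0.006
family-wise error over 1500 datasets, symmetric across tails, against a
nominal 0.0498 for 200 permutations with the observed statistic included).

## Summary statistics

Paired t tests report two-sided and one-sided p (tail beyond the observed
statistic) and paired Cohen's d = mean(diff)/SD(diff) ≡ t/√n. Partial eta
squared is F·df₁/(F·df₁+df₂). Both identities reproduce, at 3-decimal
rounding (half away from zero), every printed (t, d) pair at n = 20 and
every printed (F, df, ηp²) triple of the paradigm's group analysis — which
is also how those published values are used here: as analytic worked
examples, since the underlying patient data are not available. The
repeated-measures ANOVA is the univariate within-subject decomposition (via
pingouin); the original analysis used multivariate tests with z-scored age,
UPDRS, and disease-duration covariates, which require the real cohort and
are deliberately out of scope. The lateralization index uses magnitudes of
baseline-corrected modulations, LI = (|contra|−|ipsi|)/(|contra|+|ipsi|),
since the ratio definition is ambiguous for negative dB values; LI is
antisymmetric under hemisphere swap and undefined (NaN) when both
magnitudes are zero.

## Channel and ROI selection

Bipolar derivations are differences of adjacent contacts. The analyzed LFP
channel maximizes |start suppression| + |stop rebound| of beta power
(post 0–2 s vs pre −2–0 s), with equal weights — both criteria are stated
for the original selection but no weighting — and deterministic ties by
label order. Cortical grid points are ranked by the absolute beta contrast
averaged over subjects and the three event types; the ROI is the peak plus
its six nearest grid neighbors. Selection pools trials across
predictability conditions.

## Problem sizes and numerical defaults

The Monte-Carlo suites run at sizes chosen as package defaults: type-I
calibration 200 cohorts × 20 subjects × 60 trials with 200 permutations;
effect detection 100 cohorts × 10 subjects × 16 trials; Granger direction
recovery 100 runs × 60 trials; kinematics recovery 14 subjects × 2
conditions × 72 trials (~1000 start trials per condition); modulation/LI
recovery 20 subjects × 40 trials. Degenerate inputs raise early:
zero-variance differences (paired t), single subjects (cluster test),
non-Hermitian cross-spectra, non-finite encoder samples (with the offending
index), epochs too short for the analysis window (with the required span).

## Known limitations

- The cluster test's exactness relies on per-subject sign symmetry under the
  null; systematic (non-zero-mean) baseline artifacts common to all subjects
  are detected as real effects, by design.
- Granger estimates are pairwise (no conditional/blockwise variant, no
  phase-slope index); volume-conduction-like instantaneous mixing is handled
  only through the time-reversal contrast.
- The univariate rmANOVA does not apply sphericity corrections; the
  covariate-adjusted analyses of the original cohort are not reproduced.
- Wavelet/Hilbert alternatives and 1/f parameterization are out of scope.
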