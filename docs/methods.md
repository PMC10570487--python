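# Methods

`ibsync` analyses two-person ("hyperscanning") EEG + eye-tracking recordings
made while a dyad performs a remote joint-attention search task with a
shared-gaze channel.  This note documents the models, estimators and design
choices, what the synthetic generator does and does not emulate, and the
numerical conventions.

## The paradigm being modelled

Each trial is 13 s: a 3-s fixation cross, a 300-ms auditory word stimulus,
and a 10-s search window (starting at stimulus onset) on a 4 x 4 matrix of
alphanumeric characters containing 1, 3 or 5 targets.  Three interaction
modes — single-player (player + observer), cooperation, competition — are
played in 2 runs of 20 trials each (40 trials per mode).  Both participants'
gaze points are rendered on both screens, creating a pseudo-mutual-gaze
channel.  EEG is 32 channels per head (extended 10-20 montage) at 250 Hz
after downsampling.

## Interbrain connectivity

For band b with edges (lo, hi) — delta 1–3, theta 4–7, alpha 8–12,
beta 13–30, gamma 31–50 Hz — epochs spanning [-3, 10) s around stimulus
onset are band-pass filtered and converted to analytic signals; the argument
of the analytic value is the instantaneous phase φ ∈ (-π, π].  With
Δφₙ(t) the cross-brain phase difference of channel pair (i, j) on trial n,

- PLV(t)  = |(1/N) Σₙ exp(i Δφₙ(t))|,
- ciPLV(t) = |Im V(t)| / sqrt(1 − Re V(t)²),  V = mean phasor,
- wPLI(t) = |Σₙ Im Sₙ(t)| / Σₙ |Im Sₙ(t)|,  S = cross-spectrum,
  with the 0/0 case defined as 0 (pure zero-lag coupling carries no lag
  information).

PLV is computed per time sample across trials (time-resolved); a
trial-resolved variant (modulus over time within trial, averaged over
trials) exists but is not the default, because event-related time courses
are the primary readout.  Event-related summaries average the 200–500 ms
window (endpoint samples included, 76 samples at 250 Hz); baseline
correction subtracts the [-3, 0) mean per pair.  The 32 x 32 cross-brain
pair grid is aggregated into five scalp regions (frontal 11, central 3,
temporal 6, parietal 9, occipital 3 channels).  The central group is
{C3, Cz, C4}: published region lists sometimes name C5, which does not
exist in this montage while C4 would otherwise be unassigned; the
substitution is recorded in output metadata.

The "PLV" here is the standard Lachaux formulation (modulus of the
trial-averaged unit phasor).  A literal arithmetic mean of |Δφ| would not
have the 0–1 range that the measure is defined to have.

## Preprocessing

Band-pass FIR (windowed-sinc, Hamming): transition width 1 Hz for edges
below 8 Hz, 25% of the edge above; kernels are odd-length, applied by FFT
convolution on odd-mirror-extended signals with group-delay compensation,
so filtering is zero-phase.  Hamming gives ≥ 50 dB stopband and < 1%
passband ripple.  Downsampling is polyphase with anti-aliasing
(`scipy.signal.resample_poly`).  Re-referencing subtracts the mean of TP9
and TP10 from every channel; note that after this reference TP9 and TP10
are algebraically degenerate ((TP9−TP10)/2 and its negative) — the pipeline
reproduces the mean-mastoid choice and flags the degeneracy in epoch
metadata rather than resolving it.  Epochs are half-open [tmin, tmax) so
sample counts are exact ((13 s)(250 Hz) = 3250).  Component-based artifact
cleaning (ASR, ICA/ICLabel) is out of scope: those are external EEGLAB
tools; `preprocess_recording(precleaned=...)` accepts externally cleaned
signals, and synthetic data is generated clean.

## The shuffled-team bootstrap null

Whether true partners' brains are more phase-locked than chance is tested
by re-pairing participants who never interacted: D dyads give
C(2D, 2) − D pseudo-dyads (29 dyads → 1624).  Pseudo-dyad connectivity is
computed exactly as for true dyads, with trials matched by position within
mode (every dyad saw the identical stimulus sequence).  Per channel pair,
1000 bootstrap means of m = 200 draws (with replacement — the natural
reading of "bootstrap"; drawing without replacement is not implemented)
form the null distribution; the group mean of the true-dyad values is
scored as z = (mean_true − mean(boot)) / sd(boot) and a two-sided
percentile p with add-one correction, p = 2·min(r+1, B+1−r)/(B+1).
Benjamini–Hochberg FDR corrects across the 1024 channel pairs.  One root
seed spawns per-(band, pair) child generators, so results are reproducible
under any execution order.

**Calibration caveat.**  The bootstrap spread sd(boot) ≈ sd_shuffled/√m
describes the uncertainty of a 200-sample mean, not the sampling noise of
the true-dyad mean, which is ≈ sd/√D.  Whenever D ≪ m the z statistic is
inflated by roughly √(m/D) under the global null, and the percentile test
is strongly anti-conservative: on fully uncoupled simulated dyads (D = 8)
the package measures a rejected-pair fraction of ≈ 0.6–0.7 at q = 0.05
instead of ≈ 0.05.  This is a property of the procedure as published (the
study used D = 29, m = 200), not of this implementation; the corresponding
acceptance test is expected to fail and is kept failing rather than
weakened.  Passing `m=None` to `dyad_null_test` matches m to the number of
true dyads, which restores approximate calibration and is the variant we
recommend for new analyses; it is not the default precisely because the
default reproduces the published procedure.

## Behavioral metrics

A target is "locked" after a strictly greater than 700 ms continuous
within-cell dwell; its lock onset is therefore 700 ms before the
identification event.  The first target-searching time (TST) runs from
stimulus onset to the first lock onset and TSTₖ from one onset to the next.
Identifications earlier than 700 ms after the stimulus clamp the onset to
the stimulus and are flagged.  Summaries use a 10% trimmed mean implemented
as ceil(0.05 n) values removed per tail (per-tail vs total is not fixed by
convention; this choice is configurable), with a flagged median fallback
when trimming would empty the sample.

Dist_gaze interpolates both gaze tracks onto a common uniform clock
(validity propagates: a resampled point is valid only when both neighbours
are) and averages the per-sample Euclidean distance — by default over the
10-s search window only, since the fixation period would dilute the mode
contrast; full-trial averaging is available and matters when matching
deposited data.  Heatmaps are occupancy histograms on a 96 x 54 cell grid
(20-px cells at 1920 x 1080), Gaussian-smoothed (default σ = 20 px) and
normalised to unit mass.  Similarity: Pearson r of flattened cells (nan on
zero variance), SSIM on max-rescaled cells (7 x 7 window, standard
stabilising constants), and Jaccard of supports binarised at the uniform
density 1/(H·W) — cells occupied above chance; the threshold is a
convention, reported with the output.

## Condition contrasts

One-way repeated-measures ANOVA (F = MS_factor / MS_(factor×subject)) with
Holm–Bonferroni paired post hocs, and mixed factorial ANOVA (mode within,
gender composition between), delegated to pingouin behind a stable
interface; the test suite checks both against hand-written sums-of-squares
oracles.  No sphericity correction by default (Greenhouse–Geisser is an
option).  Singleton between-groups (e.g. a lone male–male dyad) must be
excluded by the caller; the error message says so.  Subjects missing factor
levels are dropped and counted in the result's notes.

## The synthetic dyad generator

Each channel is a sum of band-limited oscillators plus 1/f background
noise (default 2 µV RMS; band amplitudes 8/6/10/4/2 µV for δ/θ/α/β/γ,
ordinary resting-EEG magnitudes).  Within a band, participant A's phase
ramps at the band centre frequency with a slow Brownian jitter
(0.02 rad/sample) and a fresh start phase per trial and channel.
Participant B's phase equals A's plus one band-level offset (drawn away
from 0 and π so coupled pairs have a genuine, lag-visible phase lead) plus
wrapped-normal noise drawn once per trial: σ_event inside the
post-stimulus window (default the first second after the stimulus),
σ_base elsewhere.  The asymptotic PLV of a coupled pair is exactly
exp(−σ²/2); at 40 trials the finite-sample expectation is obtained from a
Monte-Carlo oracle that draws the same wrapped-normal model directly.
Uncoupled bands/modes give B an independent uniform offset per trial and
channel, which lands estimated PLV at the finite-trial uniform-phase floor
(≈ √(π/4N) for N trials).

The offset and trial noise are shared across a band's channels.  This is
what makes the closed form survive mean-mastoid re-referencing: any linear
within-head re-reference rotates both heads' band phasors identically.
With per-channel offsets (an earlier design), re-referencing mixes
same-band oscillators whose relative phases change every trial and the
target is unrecoverable even at σ = 0.

Default coupling emulates the empirical pattern: δ and θ carry coupling
(σ_base/σ_event = 1.1/0.55 cooperation, 1.2/0.75 competition, 1.3/1.0
single-player); α, β, γ are uncoupled.  These are generator conditions
chosen once, not fitted values.

The background noise enters every channel twice — directly and through the
noisy mastoid reference — and attenuates measured PLV by ≈ 0.04 at the
default SNR.  This is measurement attenuation, not estimator bias; the
parameter-recovery experiment therefore runs the generator noise-free,
which is the configuration the closed-form target describes.  Recovery
also uses *stationary* coupling (a zero-width event window): with a
within-trial σ switch, the band filter's several-second support mixes
pre-switch phase noise into windows near the switch, pulling the estimate
below the constant-σ oracle — visible in the README example, where the
200–500 ms estimate sits below the asymptote.  The event-locked modulation
itself is validated separately (event-window PLV exceeding baseline for
σ_event < σ_base).

Gaze: 30 Hz (consumer eye-tracker class; the acquisition rate is not part
of the paradigm definition and is configurable), 1920 x 1080 screen with a
720 x 720 px matrix centred (180-px cells).  Players scan cells in random
order (0.12–0.28 s distractor dwells, 0.15–0.35 s initial reaction time,
saccade speed 5000 px/s, 6-px fixational jitter) and mark targets by
dwelling 0.85 s (> the 0.7-s lock threshold).  Partner B's step is a convex
combination of its own search drift and attraction × the unit vector toward
A (default +0.8 cooperation, −0.8 competition, 0 single); repulsion is
proximity-gated (e-folding 250 px), i.e. an avoidance force, so competitors
avoid each other's neighbourhood while both remain on the task area.  In
single-player mode the observer is a mean-reverting free drift over the
whole screen and only the player emits locks; in competition both
participants search and each target goes to whoever locks it first; in
cooperation marking is led by A (the emergent leader) and B follows.

What the generator does **not** emulate: eye-movement artifacts in EEG,
realistic scalp topographies or volume conduction (available only as an
explicit within-head mixing matrix), ASR/ICA behaviour, blinks/dropout in
gaze validity, learning or fatigue across runs.  Tests passing on this
generator therefore validate the estimators and the pipeline's contracts,
not artifact robustness on real recordings.

## Problem sizes used by the experiments

All experiments keep the paradigm's per-condition structure (40 trials,
32 channels, 250 Hz, epochs [-3, 10)) and scale the dyad count: parameter
recovery uses 4 dyads per σ, zero-lag discrimination 8 dyads, null
calibration 8 dyads × 20 replicates (10 in the reproduction script), and
behavioral orderings 4 dyads.  These sizes put every Monte-Carlo tolerance
well below the effects being checked while keeping a full run on one CPU
in minutes.

## Numerical conventions and edge cases

- Unit phasors are formed with an eps-guarded modulus; ciPLV's denominator
  clips 1 − Re V² at machine eps.
- wPLI 0/0 → 0; an all-real cross-spectrum is reported as no lag coupling.
- Bootstrap with sd = 0 yields a ±inf z sentinel and the percentile p.
- Trimmed mean falls back to the median (flagged) when trimming would
  empty the sample; n = 1 returns that value.
- XDF reading applies the mean clock offset per stream and aligns both EEG
  streams to the later start, resampling to the lower rate when they
  differ; non-monotone marker clocks are an error, not a warning.
- Truncated or foreign container files raise an integrity error rather
  than returning partial data.
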