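# Methods

This note documents the models, numerical choices and limitations behind
`fatigueloop`. It is written for someone who wants to trust (or challenge)
the pipeline's behaviour, not just call it.

## Problem setting

During robot-assisted, electrically stimulated therapy, sustained effort
fatigues the muscle: the surface-EMG power spectrum compresses toward lower
frequencies and voluntary torque output falls. A closed-loop stimulator
should detect this and back off — stimulating a fresh muscle harder
(25–30 mA) and a fatigued one more gently (12–17 mA) — instead of applying a
fixed open-loop intensity. The package implements that loop offline, from
signal synthesis to the stimulation command log, with the same dataflow a
real-time system would use (acquisition → processing/decision → actuation →
report).

## Synthetic sessions

Real labeled recordings of fatiguing therapy sessions are not publicly
available, so the generator produces sessions with the statistical structure
the method relies on; all defaults are the conditions used throughout the
tests.

**EMG.** The active segment is amplitude-modulated band-limited Gaussian
noise built by 50%-overlap-add of Hann-windowed white-noise bursts (512
samples at 1 kHz), each shaped in the frequency domain by a Gaussian band
(σ = 15 Hz) whose center follows a linear mean-frequency schedule, 90 → 70 Hz
by default. A Gaussian band centered at f_c has spectral centroid f_c, so the
programmed MF is directly verifiable with a periodogram. Each burst is
normalized to unit variance and the overlap-add window-power profile is
divided out before a linear RMS envelope (1.0 → 0.8 mV default) is applied.
A session begins with a relaxation segment (5 s default) of white noise at 5%
of the initial active RMS, emulating the calibration recording taken before
therapy. Powerline (pure sinusoid, 50/60 Hz) and motion (low-passed noise,
< 10 Hz) artifacts can be injected explicitly.

**Torque.** Active torque follows a linear fatigue schedule (1.0 → 0.7 Nm
default, i.e. −30%). Physiologically, voluntary torque is produced by the
same motor activation the EMG envelope reflects, so the realized trace is the
schedule multiplied by the normalized slow activation envelope (a 200 ms
moving average of the rectified EMG with the programmed RMS drift divided
out) plus 0.5% additive sensor noise. Window-to-window effort fluctuations
therefore appear coherently in torque and in the EMG amplitude features —
the property that makes the torque half of the labeling rule observable to
an EMG-only classifier, which is the premise of the whole method. Setting
`torque_coupling_ms = 0` gives an idealized, uncoupled linear trace (used by
tests that need a clean time-threshold criterion). With coupling on, the
*schedule* endpoints are tight (linear-fit recovery within a few percent)
while any single window's torque fluctuates ~8%, so endpoint assertions use
whole-session fits rather than single-window means.

**What the generator does not emulate:** motor-unit recruitment and firing
statistics, stimulation artifact contamination, non-monotone fatigue
trajectories (rest-recovery), electrode lift-off, multi-channel montages.
Passing tests demonstrate the pipeline's correctness and its behaviour under
the assumed structure; they do not certify classifier accuracy on real
patient EMG.

## Preprocessing

Butterworth band-pass designed as second-order sections (stable at order 4
with a 20–450 Hz band); `causal` single-pass filtering is the default because
the downstream controller is an online consumer, `zero_phase`
(forward–backward, no lag, doubled effective order) is available for offline
analysis. The moving average uses truncated windows at the signal edges: zero
padding would bias the session-start calibration statistics low. Note the
20–450 Hz band-pass removes only out-of-band interference — sub-20 Hz motion
drift is attenuated > 20 dB, but a 50/60 Hz powerline component lies inside
the pass band and survives this stage.

## Features and labeling

Windows are 200 ms long with a 100 ms step; a final partial window is
dropped. Per window: RMS = √mean(x²), MAV = mean|x|, ZC counts sign changes
where both neighbours exceed a deadband, MF is the periodogram power centroid
with the DC bin excluded, MP = mean(x²) (so MP = RMS² on a common source
signal — asserted as an identity). A single 200 ms periodogram is used for
MF; Welch averaging inside so short a window would trade bias for no useful
variance reduction.

Feature sources: amplitude features (RMS, MAV) come from the rectified,
smoothed envelope — the activation level — while frequency-bearing features
(ZC, MF, MP) come from the band-passed signal, because rectification folds
the spectrum and a non-negative envelope has no zero crossings at all (ZC
would be identically 0). A `paper_strict` mode computes all five on the
envelope for strict replication of a post-rectification chain, with that ZC
degeneration documented. The ZC deadband defaults to 3× the calibration-
segment RMS, making ZC robust to baseline noise.

Labels implement the dual criterion exactly as worded: torque decline
strictly greater than 20% (boundary value 20% is Non-Fatigue) AND MF decline
of at least 10% (boundary value 10% is Fatigue), relative to baselines
averaged over the first 10 active windows (1 s). The relaxation segment is
excluded from baselines — relaxed EMG has no meaningful MF — and a
non-positive baseline torque raises a labeling error since it means active-
torque calibration is missing.

## Classifier

Features are z-scored with population (ddof = 0) statistics fitted on
training data only; constant features are rejected by name. The SVM uses an
RBF kernel with C = 1 and γ = 1/(n_features · var), both exposed. Non-Fatigue
is the positive class, so the decision value (signed hyperplane distance) is
positive on the fresh-muscle side, matching the controller's +0.6/−0.6
convention. Cross-validation is stratified 5-fold with shuffling controlled
by a seed and the normalizer re-fit inside each training fold (no leakage;
asserted). Persistence stores support vectors, dual coefficients, intercept,
hyperparameters and normalization statistics in a versioned JSON file; the
decision function is evaluated from those arrays, so a loaded model is
bitwise-equivalent to the trained one and the loader refuses unknown format
versions. The decision-value scale is uncalibrated: the ±0.6 thresholds are
meaningful for this training scale and should be revisited if the feature
distribution changes. A 2-component PCA projection with silhouette scoring is
provided as the standard separability check of a labeled feature set.

## Controller

Crisp thresholds map the decision value to Low (> +0.6), Moderate
([−0.6, +0.6], boundaries inclusive) and High (< −0.6) fatigue. A transition
requires the candidate state to be classified in at least 2 consecutive
windows (the counter resets on any interruption and is capped at the
threshold), and at most one transition may occur per 15 s, measured from ramp
start; a sustained candidate is held and fires when the interval elapses. On
transition the amplitude ramps linearly over 4 s (center of the allowed
3–5 s band) from its current value to the new state's target. The target
within a state's range is an affine map of the clamped (±2) decision value —
deeper into fatigue means lower current — with a midpoint mode available.
The controller starts in Moderate at the range midpoint with the rate-limit
clock unset, so the first transition is never blocked. Safety invariants
(amplitude always within 12–30 mA, within the active state's range once its
ramp completes, no per-step discontinuities beyond the ramp slope) are
enforced by property tests over adversarial decision streams.

An optional secondary guard additionally requires the window MF to have
moved ≥ 10% relative to its value at the previous transition. It is disabled
by default (the two-window rule is the primary mechanism) but recommended
when decision values are noisy: the uncalibrated decision magnitude of a
correctly detected fatigued muscle can dip into the Moderate band for two
consecutive overlapping windows, and the guard suppresses those spurious
reversals, as the end-to-end tests demonstrate.

## Reporting

RPF = RoM_post / RoM_target × 10 with a 90° default target; displayed values
are rounded half-up to one decimal (82° → 9.1) with the unrounded value kept
internally. Percent change is (post − pre)/pre × 100. The Wilcoxon
signed-rank test is exact: zeros are dropped with a warning, tied magnitudes
receive midranks, the null distribution of W⁺ is enumerated over all 2ⁿ sign
assignments (n ≤ 15), and the two-sided p is the doubled smaller tail capped
at 1 — for n = 3 same-direction changes this gives 0.25, the smallest
two-sided p attainable at that sample size. Group summaries report the mean
of per-patient percent changes. Reports are emitted as JSON and Markdown
rendered from the same dictionary, so the two cannot disagree.

## Pipeline

`run_pipeline` chains the stages in-process with the same data contracts a
distributed deployment would use; every stage writes a self-describing
artifact (CSV with headers plus YAML/JSON sidecars) and logs its parameters
with a SHA-256 content hash, so any stage can be re-run from files alone.
One global seed fans out to per-stage seeds via `SeedSequence.spawn`, reduced
modulo 2³¹; a fixed seed yields byte-identical artifacts. If the labeler
produces a single class (e.g. a drift-free session), no classifier can be
trained; the controller is then replayed on neutral decisions (0.0, inside
the Moderate band) and remains in its initial state.

## Problem sizes

Tests and the acceptance script use ~35–125 s single-channel sessions at
1 kHz (≤ 601 windows), 20-seed parameter-recovery sweeps, and 10-minute
simulated decision streams for the controller property suite — sizes chosen
so the full suite completes in well under a minute of compute while leaving
every statistical check comfortably powered.

## Known limitations

- Single channel, single muscle; the acquisition montage is out of scope.
- The classifier pools all windows of a session (and would pool subjects);
  accuracy estimated this way is optimistic for unseen subjects. A
  leave-one-subject-out protocol is the natural next step once multi-session
  data exists.
- Decision-value thresholds are scale-dependent (no probability calibration).
- Only stimulation amplitude is modulated; pulse width and frequency are not.
- The generator's fatigue trajectories are monotone and linear; real sessions
  include rests and non-monotone recovery.
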