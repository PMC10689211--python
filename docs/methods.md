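# Methods

This note documents the generative model behind the synthetic data, the
estimator conventions used by the analysis stages, the numerical choices
that required a decision, and what the passing tests do and do not show
about real recordings.

## The study design being emulated

The package targets a drug-challenge design: two macaque-like subjects
("Y" and "N") perform a seven-task oculomotor battery in repeated
sessions, each session recorded under one of three injection states —
saline control, PCP, or ketamine (both non-competitive NMDA-receptor
antagonists used to induce schizophrenia-like states; typical doses in
such work are 0.3–3.0 mg/kg PCP and ~0.8 mg/kg ketamine — dose is metadata
here and does not enter the model).  The analysis unit is the session: each
session is reduced to a 31-dimensional named parameter vector, and the
question is whether the injection state is decodable from that vector,
within and across subjects.

Default study conditions: 40 sessions per state per subject; 500 Hz eye
tracking with 0.015° RMS measurement noise; per session 20 anti-saccade,
16 pro-saccade and 16 delayed-saccade trials, 3 × 8 s linear pursuit,
3 × 10 s Lissajous pursuit, 5 × 3 s fixation and 2 × 15 s free-viewing
trials.  Trial counts and session counts are unreported quantities in this
kind of study and are config fields.

## Saccade waveform model

Saccades are synthesised from a main-sequence law: peak velocity
`v_max·(1 − exp(−A/a_sat))` (defaults `v_max` = 550 °/s, `a_sat` = 5°) and
duration `22 + 2.8·A` ms, with per-saccade lognormal duration jitter
(σ = 0.08–0.10) reflecting empirical main-sequence scatter.  The velocity
profile is `sin(πt/D)^γ`; γ is solved per saccade so that amplitude,
duration and peak velocity hold simultaneously (γ = 2 is the raised
cosine).  γ is capped at 3: real saccade profiles are close to raised
cosine, and an uncapped γ under a long-duration jitter draw produces
~10 ms sub-threshold velocity tails whose onset is undefined for any
velocity-based detector.  When the cap binds, the realised peak velocity
(reported in the ground truth) gives way to the commanded one.

Displacement is accumulated from a fine-grid integral of the profile, so
the net amplitude is exact regardless of γ or sampling.

## Per-task generative models

* **Anti/pro-saccade** — central fixation, colour cue, lateral target at
  ±10°; the response saccade goes to the correct side with the session's
  accuracy probability, at a reaction time drawn around the session mean
  (clipped normal, SD 45 ms); 2% of trials are non-responses.
* **Delayed saccade** — target appears 600 ms before the go signal;
  fixation breaks during the delay occur with a per-session Bernoulli
  probability and abort the trial (scored incorrect).
* **Linear pursuit** — triangular target sweep at 10 °/s over ±8°; smooth
  eye velocity is gain × target velocity; catch-up saccades fire as a
  Poisson process with rate `0.3 + 5·(1 − gain)` Hz and amplitude equal to
  the accumulated position error at trigger time (skipped below 0.3°).
* **Lissajous pursuit** — target `x = 8°·sin(2π·0.2t)`,
  `y = 8°·sin(2π·0.3t)`; per-axis gains with a small (0.08 rad) phase lag;
  catch-up saccades as above on the 2-D error vector.
* **Fixation** — smooth ocular drift (AR(1) velocity with 120 ms time
  constant through a 1 s leaky recentring integrator; stationary position
  SD ≈ 0.25° under saline), microsaccades at ~1.3 Hz with lognormal
  amplitudes (mode ≈ 0.3°, clipped to [0.18°, 1.8°]) whose directions mix
  a downward von Mises component (mean 270°, κ = 4, probability `p_down`)
  with a uniform background; pupil trace
  `b·(1 − r·(1 − e^{−t/τ}))`, τ = 600 ms.
* **Free viewing** — saccades at a state-dependent Poisson rate with
  subject-specific lognormal amplitude distributions (subject Y mode
  ≈ 0.7°, subject N mode ≈ 6°) and a downward direction bias; gaze is
  steered back toward the subject's habitual loci when it leaves ±11°.
* **Auditory oddball EEG** — each epoch is a three-Gaussian ERP template
  (P50 +2 µV @ 50 ms, N100 −4 µV @ 100 ms, P200 +4.5 µV @ 185 ms) scaled
  multiplicatively by tone intensity (60 dB → 0.6, 80 dB → 1.0), pitch
  (1200 Hz → 0.75, 1500 Hz → 1.0), state gain and — for deviants — a
  deviant gain, plus 1/f-amplitude noise (per-epoch SD 8 µV for the
  skull-electrode subject, 20 µV for the scalp-electrode subject) and a
  random DC offset.  Oddball sequences keep ≥ 2 standards between
  deviants.

## Drug-state parameterisation

Each state is a full parameter set (saline = baseline); sessions scatter
around the state means with the SDs in `SessionScatter`.  Effects follow
the directions established for NMDA-antagonist challenges: both drugs
lower anti-saccade accuracy (0.82 → 0.62 PCP / 0.68 ketamine) and lengthen
reaction times (+70/+50 ms), slow saccades (velocity scale 0.85/0.90) and
prolong them (duration scale 1.18/1.08), lower pursuit gains
(0.92 → 0.72/0.78 linear, similar per-axis Lissajous) while raising
catch-up saccade rates, enlarge and speed up microsaccades and bias them
downward (`p_down` 0.25 → 0.55/0.50), enlarge the BCEA (PCP robustly;
ketamine heterogeneously across subjects, ×1.3 in Y but ×0.9 in N),
shrink the pupil and its constriction response, lower the free-viewing
saccade rate, amplify the AEP (gain 1.35/1.25) and reduce the deviant
(MMN) gain (1.25 → 1.05/1.12).  Saccade amplitude moves in opposite
directions under the two drugs (×1.07 PCP, ×0.93 ketamine), which is one
of the features separating them.

A per-session latent couples accuracy and reaction time: under saline a
"caution" latent (slower sessions are more accurate — the classical
speed–accuracy trade-off), under drug a "severity" latent (slower sessions
are also less accurate), flipping the sign of the across-session
accuracy-vs-RT correlation.

Effect magnitudes were calibrated once, at design time, to make
the documented drug-effect directions decodable at the default session counts, and left
untouched thereafter.  `GeneratorConfig.null_effects()` replaces every
state with the saline parameter set, which is the negative-control world
used by the chance-level tests.

## Estimator conventions and their calibration

* **Velocity** — five-point smoothing differentiator
  `(x[i+1]+x[i+2]−x[i−1]−x[i−2])·fs/6` after an optional 3-sample boxcar.
  Exact for linear signals; attenuates the peak of a 50 ms saccade profile
  by ~3% (plus ~1% for the boxcar), which is why session-level velocity
  features use net displacement ÷ duration rather than sample speeds.
* **Event extent** — threshold runs are merged (< 20 ms apart), dropped
  (< 8 ms), then extended outward while speed decreases and stays above
  1.7 °/s, with clamped zero-crossing extrapolation for sub-sample
  onset/offset.  The 1.7 °/s cutoff was calibrated on noiseless generator
  output to make microsaccade duration unbiased (and onsets accurate to
  ≤ 4 ms at 500 Hz) for the sin^γ profile family; it is a config field and
  may need recalibration for a different tracker/noise regime.
* **Adaptive threshold** — per-axis robust SD via the median estimator
  `sqrt(median(v²) − median(v)²)`, λ = 6, combined elliptically, with a
  5 °/s per-axis floor so noiseless input does not degenerate.
* **Reaction time** — go (for anti/pro trials the target onset is the go)
  to onset of the first detected saccade with amplitude ≥ 2°; trials
  without one are no-response and count as incorrect without an RT.
* **Pursuit gain** — desaccaded samples (10 ms pad) later than 200 ms
  after motion onset; linear gain additionally excludes samples where the
  target moves slower than half its nominal speed (reversal
  neighbourhoods); Lissajous gains come from least-squares cos/sin fits of
  eye and target velocity at the target frequency (inferred from the
  commanded channel's zero crossings when not given).
* **BCEA** — all gaze samples of the trial (not desaccaded), P = 0.68,
  sample SDs with ddof = 1.
* **Blinks** — gaps ≤ 50 ms are linearly interpolated; trials with longer
  gaps are excluded from session aggregation.
* **Decoder** — z-scoring uses the training fold only; PCA components get
  a deterministic sign (largest-|loading| entry positive); ANOVA ties
  break toward the lower component index; the SVM is `SVC(C=1, rbf,
  gamma="scale")`, one-vs-one.  The drug-vs-saline contrast pools PCP and
  ketamine into one class.  Cross-subject transfer fits the scaler and PCA
  on the pooled unlabeled two-subject matrix — this isolates
  inter-individual baseline variance into its own component, which the
  train-subject-only ANOVA selection then discards; the strict
  train-only-everything variant is available (`shared_space=False`) but is
  defeated by the subjects' very different free-viewing amplitude
  baselines.

## What the synthetic data does and does not establish

The generator provides exact ground truth (every injected saccade, every
session parameter), which is what makes recovery testing possible at all.
It emulates main-sequence kinematics, oculomotor drift, state-dependent
parameter shifts, session-level scatter, subject heterogeneity, blinks and
tracker noise.  It does **not** emulate: pursuit initiation dynamics or
anticipatory pursuit, saccadic curvature or post-saccadic oscillations
(glissades), slow drug washout within a session, correlated trial-history
effects, eyelid artefacts beyond simple gaps, or realistic EEG topography
(a single-channel template-plus-1/f model stands in for the evoked
response).  Passing recovery tests therefore show the estimators are
correct for signals with these statistics, not that the thresholds are
optimal for any particular real tracker; all thresholds are config.

Decoding accuracies on the default synthetic study (≈ 99–100%) exceed
what real recordings give (~90%+), because the generator's session
scatter is well-behaved and stationary; the meaningful checks are the
negative controls (chance level under null effects and label permutation)
and the recovery tolerances, not the absolute accuracy.

## Numerical details

* Hierarchical seeding: every session draws its RNG from
  (root seed, subject index, state index, session index); AEP conditions
  from (root seed, marker, state, subject, tone, role, block).  Identical
  config ⇒ byte-identical outputs, including written TSVs.
* PCA uses the full SVD solver; reconstruction from all components is
  exact to float precision.
* Degenerate guards: zero-variance features get unit scale before
  z-scoring; constant PC scores get ANOVA p = 1; all-zero loadings rank
  features alphabetically with zero weight.
* LOOCV folds that lose a class entirely are skipped with a warning
  (cannot occur at the default session counts).
* Rank-sum masks use the normal approximation (`scipy.stats.ranksums`)
  pointwise with no multiplicity correction, mirroring exploratory
  per-point significance ticks; the null false-positive rate was verified
  at ≈ 1% by simulation.
* The MMN index is a window mean (100–200 ms) of the deviant − standard
  difference, not a peak measure; at realistic 1/f noise it needs
  trial counts in the thousands to resolve.

## Known limitations

* The fixation ground truth for BCEA is the realised closed form on the
  generated gaze (the drift process's finite-window covariance has no
  convenient closed form); the independent closed-form check is done
  against i.i.d. Gaussian scatter instead.
* Catch-up saccade rates are recovered with a small negative bias (the
  smallest catch-ups fall below the fixed detection threshold); gain
  recovery is unaffected.
* Pupil units are arbitrary (tracker-dependent); only within-study
  contrasts are meaningful.
* The free-viewing gaze histogram is QC output only and deliberately
  excluded from the decoder feature set (it encodes subject habit, not
  state).
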