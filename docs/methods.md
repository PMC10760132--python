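# Methods

This note documents the models and procedures implemented in `tmrsim`, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices that matter for reproducing results.

## Synthetic sleep EEG (`synth_eeg`)

**Hypnogram.** Naps are scored in 30-s epochs over {W, N1, N2, N3, REM}. The
generator is a semi-Markov progression: an initial wake period (1–3 min),
descent W → N1 → N2 → N3, returns to lighter stages with configurable
probabilities, and REM permitted only after 60 min (daytime naps rarely reach
REM earlier). A `force_stage` override produces degenerate hypnograms
(e.g. all-wake controls).

**Signal model.** One virtual Fz channel at 512 Hz (µV units, seconds from
recording start). The trace is the sum of

- broadband 1/f background (12 µV RMS, exponent 1),
- a stage-dependent 0.5–2 Hz component (6 µV RMS in N2, 14 in N3) so that N3
  carries realistic low-frequency dominance,
- planted **slow oscillations**: single-cycle biphasic waves
  `−A·sin(2πt/D)` (trough then positive peak), D = 1.25 s, peak amplitude
  uniform 45–110 µV, Poisson-placed at 3/min in N2 and 7/min in N3 with a
  2 s inter-onset floor,
- planted **spindles**: Hann-windowed 11–16 Hz bursts, 0.5–2 s, envelope
  amplitude 20–45 µV, 2.5/min in N2 and 1.2/min in N3, with a 3 s
  inter-onset floor so the protocol's 2.5 s refractory gate is exercised on
  both sides.

Event densities are conventional adult NREM values; nothing in the upstream
study characterizes its participants' densities, so these are explicit
config, not data-derived. The morphology is deliberately minimal: the SO
waveform only needs a realistic rising threshold crossing and local maximum,
and the spindle only a band-limited RMS bump. Consequently, passing tests
demonstrate protocol correctness and statistical calibration — they say
nothing about detector performance against real polysomnography (no
artifacts, no alpha intrusions, no sweat/ECG contamination, single channel).

Determinism: `(config, seed)` fully determines samples, hypnogram, and the
planted-event list. An offline oracle (`offline_so_peak`: zero-phase 0.5–4 Hz
Butterworth + windowed argmax) recovers ≥ 95% of planted SOs above 50 µV
within ±0.15 s; this oracle, not the online path, defines ground truth in
tests.

## Online detection (`online_detect`)

All detectors are strictly causal and chunking-invariant: state is carried
across arbitrary chunk boundaries and output events are identical for any
partition of the same samples.

**SO up-state trigger.** The stream is filtered with a causal 2nd-order
Butterworth band-pass, 0.5–4 Hz by default (the band is a config decision —
online systems in this literature inherit it from prior implementations).
When the filtered signal rises through +35 µV the detector arms; the first
local maximum thereafter — smoothed first difference (3-sample moving mean)
changing sign from + to − — fires the trigger. The trigger is emitted within
a 16-sample latency budget of the running maximum, and the detector re-arms
only after the signal falls back below threshold (hysteresis; one trigger
per up-state). A causal filter cannot be zero-phase: the group delay at SO
frequency (0.8 Hz) is ≈ 0.31 s, so online peak times lag the offline
zero-phase argmax oracle; the documented agreement bound used in tests is
0.35 s, and ≥ 95% of large planted SOs meet it.

**Spindle detector.** Causal 11–16 Hz band-pass → moving RMS over 0.3 s → a
spindle is confirmed when the RMS stays above threshold for ≥ 0.4 s. The
threshold is an absolute 10 µV RMS by default, with an optional adaptive mode
(mean + k·SD of the RMS over a trailing 60 s). Because the causal moving RMS
reports its window's trailing edge, reported onsets/offsets are shifted back
by half the window. `last_spindle_time(t)` returns the most recent moment a
confirmed spindle was ongoing at or before `t` — measured from the spindle's
running end, which is the conservative choice for the refractory gate — and
never uses information past `t`.

## Cueing protocol (`cue_protocol`)

**Plan.** Of ≥ 3 stimulus categories, one is assigned to interleaved cueing,
one to blocked cueing, the rest stay uncued; one random exemplar per cued
category is held out. Each cueable item is scheduled for 18 repetitions
(the protocol's per-item ceiling; realized counts are truncated by how much
NREM the nap actually contains). Interleaved items rotate round-robin;
blocked items are grouped (all repetitions of one item before the next). The
two cued categories are intermixed by alternating blocks of 18 slots — this
satisfies both "intermixed across the nap" and the per-category order
definitions; no finer rule is specified anywhere, so this is a documented
design choice. A sham ("no sound") slot is inserted after every 6th sound
slot; shams pass through the identical gate and serve as the within-subject
control.

**Gate.** A cue (or sham mark) is delivered iff *all* of: SO trigger
present ∧ stage ∈ {N2, N3} ∧ armed ∧ (now − last spindle ≥ 2.5 s) ∧
(now − last cue ≥ 8 s). Arming requires 180 s of N2; the clock counts
contiguous time (N3 keeps a started run alive, any W/N1/REM resets it —
whether the original protocol required contiguity is not stated, so the
choice is config-exposed via `arming_contiguous`). Arming is one-shot, as in
a system switched on by an experimenter; subsequent stage excursions merely
gate delivery. Cueing resumes mid-plan after an interruption (the next
undelivered slot), also config-visible behavior.

The session runner makes a single causal pass; the event log records, per
delivered cue/sham, the stage, the causally filtered amplitude at the
trigger, the spindle gap, and the within-item repetition index, so every
gating invariant is checkable post hoc. Sequence positions label the last
four *fully* cued blocked items 1…4 counting from the nap's end (4 = last);
uncued-category items are position 0.

## Cue-locked spectral statistics (`tfr_stats`)

Epochs are cut −3…+3 s around events after zero-phase 0.3–30 Hz filtering
and polyphase resampling to 256 Hz of the whole recording (filtering before
cutting avoids per-epoch edge transients). An extended −2…+6 s window is a
config preset. Artifact rejection is a two-stage AND rule — an epoch is
removed only when it exceeds ±300 µV *and* is a variance or kurtosis outlier
(|z| > 3 across epochs) — an automated surrogate for manual screening plus
outlier confirmation; the original manual criteria are irreproducible and
this surrogate is labelled as such.

Spectral power uses convolution with 5-cycle Hanning-tapered complex
exponentials on a 4–30 Hz grid in 0.5 Hz steps (53 bins) sampled every 5 ms.
Bins whose taper extends past the epoch are marked invalid (NaN), not
zero-padded. Each frequency row is converted to percent power change against
the −300…−100 ms pre-event baseline; because the baseline is computed from
the same sampled grid, the baseline-window mean of the output is zero to
machine precision. Sound-minus-sham difference maps are formed per subject
before group statistics.

**Cluster-size permutation test.** Per bin, a one-sample t across subjects;
bins beyond the two-sided α = 0.01 critical value form 4-connected candidate
clusters separately per sign (4-neighborhood: standard and conservative).
Each candidate's size in bins is referred to the permutation distribution of
the maximum cluster size across both signs under random whole-subject sign
flips (1000 permutations by default; p ∈ [1/(n_perm+1), 1]; significance
p ≤ 0.05). Cluster *mass* (sum of |t|) is available via `statistic="mass"`.

**Known limitation — conservatism on white null data.** On spatially
independent null maps the suprathreshold field at α = 0.01 is sparse, so the
null maximum cluster size concentrates on {1, 2} with
P(max ≥ 3) ≈ 0.015; the size statistic can then only reject at size ≥ 3 and
the realized family-wise error rate is ≈ 0.015 rather than the nominal 0.05.
This is a property of the discrete statistic, reproduced bin-for-bin by an
independent implementation (MNE's cluster test with `t_power=0`), not an
implementation artifact: the test *controls* FWER (never exceeds nominal)
but is conservative on white noise. On smooth, realistically correlated
maps the statistic is far less discrete. The mass statistic is near-exact on
white noise; size remains the default because it is the procedure this
package models.

The ERP is the trial mean after 0.5 Hz zero-phase high-pass, baselined to
−200…0 ms.

## Behavioral design and generator (`behavior_sim`)

Stimuli: 3 categories × 5 satellites × 5 feature slots; one prototype per
category (all category-typical features); each non-prototype has 4 shared
features and one globally unique feature in a random slot. The feature test
offers six alternatives, so chance is 1/6 ≈ 0.167.

Schedules: learning runs in 45-trial blocks, sampling unique slots with
weight 2.21 relative to shared slots (the realized ratio is stochastic per
block and converges to the weight ratio over many blocks); the stopping rule
is a pure function — stop at ≥ 66% in a block, or ≥ 50% once 60 min have
elapsed. The test schedule queries, per non-prototype, its unique feature
twice and each shared feature once across three trials; prototypes get two
trials of two distinct shared features; novel satellites (default 3, one per
category — their number is a design choice, not a reported quantity) are
queried on one shared feature; no satellite appears on consecutive trials.

The data generator emits item × feature-type accuracy rows, pre and post
nap, as binomial proportions over the schedule's query counts (unique: 2,
shared: 4) on underlying probabilities

```
p_pre  = clip(base[ft] + subject_effect + item_effect)
p_post = clip(p_pre + drift[ft] + planted cueing effect)
```

Defaults are the simulated study's operating conditions: pre-nap base
accuracy 0.79 (unique) / 0.47 (shared); planted cued-item effects
δ_unique = +0.12 and δ_shared = −0.05, whose sum (0.17) is the cueing ×
feature-type interaction on the uncued-reference / shared-reference coding;
a spread fraction of 0.6 of that effect for never-cued items in cued
categories; cue counts per item from a clipped normal (mean 7.59, SD 2.90,
range 1–18); subject and item SDs of 0.06. `drift` absorbs all non-cueing
pre-to-post change and is calibrated so population pre/post means resemble
the observed ones. Optional structure: blocked/interleaved effect
multipliers (default equal), a per-position gradient for blocked items
(default 0), a per-cue increment (default 0), and a plantable within-object
tradeoff in which the post-nap shared probability is tied linearly to the
*observed* unique accuracy, making the planted observed-scale regression
slope exact in expectation. Confidence ratings are a noisy monotone
transform of the accuracy probability onto a 1–5 scale. Setting
`binomial_sampling=False` removes observation noise entirely (accuracies
equal probabilities), which the tests use for exact-zero contracts.

The generator does not model learning dynamics, item difficulty structure,
feedback effects, or response times; recovery results certify the estimation
pipeline, not psychological theory.

## Mixed-model suite (`behavior_stats`)

`prepare_model_frame` applies each variant's inclusion rules (an item counts
as *cued* only if in a cued category and cued ≥ 1 time; style models require
≥ 4 cues; sequence-position models keep only fully cued blocked items plus
uncued items and drop the repetition covariate; the novel-item variant drops
the feature-type term; an optional filter restricts to items whose pre-nap
shared accuracy ≥ unique accuracy), centers `times_cued`, and raises a
`DegenerateDesignError` naming any empty level. Fitting is delegated to
statsmodels `MixedLM` (REML, subject random intercepts). The default
optimizer can fail silently near a singular random-effect covariance, so the
model is fit with two optimizers and the better finite REML likelihood is
kept; fixed effects agree with R's `lmer` to ~1e-4 on test data.

Coefficient tests use the normal approximation to the t distribution
(`ModelResult.df_method == "normal"`): Satterthwaite and Kenward–Roger
degrees of freedom are not available in this backend, and at the row counts
involved (hundreds of observations) the approximation changes p-values in
the third decimal at most. Estimated marginal means are computed on the
factor grid at mean covariates from the coefficient vector and its
covariance; pairwise comparisons use Tukey's studentized-range adjustment
with large-sample residual df. Model diagnostics are reported as residual
summary statistics (mean, SD, skew, kurtosis), not plots, for testability.

Tradeoff slopes: per subject, the OLS slope predicting an object's
shared-feature accuracy from its unique-feature accuracy across studied
non-prototype objects; subjects with < 2 usable objects or zero variance in
unique accuracy are excluded; the mean slope is tested against zero and
pre/post slopes compared pairwise.

## Problem sizes used in checks

The repository's verification scripts use sizes chosen to give stable
estimates at interactive runtimes: one 90-min session for protocol
invariants; 200 null datasets × 500 permutations for permutation
calibration; 100 replicate 34-subject datasets for interaction recovery
(standard error of the mean ≈ 0.005); 10⁴ learning trials for the sampling
ratio. Moment-matching tests for the generator run at 500–800 subjects,
where planted effects are recovered with bias well under 10% of the plant.
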