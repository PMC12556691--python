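# Methods

This note documents the models and procedures implemented in `dyadsync`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Kinematic synchrony and complexity

**Pose representation.** A mover is 7 named upper-body joints (neck,
shoulders, elbows, hands) with 2-D pixel coordinates per frame at 25 fps.
Trajectories are optionally Savitzky–Golay smoothed (window 13 frames,
polynomial order 2 — the settings used for keypoint-tracked stimuli at
this frame rate) before metrics are computed; smoothing can be disabled
with `smooth_before_metrics=False`.

**Synchrony score.** Per frame, the 21 pairwise Euclidean joint
distances are divided by their sum (L1 normalisation). Distances remove
absolute position; the normalisation removes overall scale, so
differences in body size or camera distance cancel. Two movers' pose
vectors are compared with total-variation similarity
`s = 1 − ½·Σ|aᵢ − bᵢ| ∈ [0, 1]`, which is exactly 1 for identical pose
shapes and 0 for disjoint support; the frame average is the video's
objective synchrony `S`. The comparison function and normalisation are
documented design choices: only the endpoint behaviour (0 = no
similarity, 1 = identical) is externally fixed, and TV similarity on
L1-normalised non-negative vectors achieves both endpoints exactly while
being metric-based. Frames in which all joints coincide (tracking
dropout) receive the uniform vector and a `degenerate` flag rather than
an error.

**Movement complexity.** Sample entropy SampEn(m=2, r=0.2·SD) of each
hand's x and y series for both movers (8 series), averaged. The template
counting follows the Richman–Moorman convention (both match counts over
the first n−m templates, Chebyshev distance, self-matches excluded),
verified identical to the R `pracma` implementation and to an exhaustive
brute-force oracle. A constant series scores 0; if no (m+1)-length pair
matches, the result is +inf; m and r_factor are exposed.

## Estimation-error models

Estimation error is `D = 100·S − E` (positive = underestimation).
Predictor standardisation uses z-scores with the sample SD (n−1),
computed once across the analysed sample — traits at participant
level — not per condition, which keeps interaction terms interpretable.

Both behavioural models are Gaussian hierarchical regressions with a
participant random intercept:

* **Trait model**: `D ~ 1 + condition + Σ traitₖ·condition + (1|ID)`,
  six z-scored traits (extraversion, self-esteem, body perception, body
  competence, empathy, autistic traits). Reported quantities are the
  per-condition mean errors, their contrast (performed − unknown), and
  per trait the condition-averaged slope and between-condition slope
  difference, all computed draw-wise from the coefficient posterior.
* **Rating model**: `D ~ 1 + enjoyment·condition + complexity·condition
  + recognized + (1|ID)`, enjoyment and complexity in raw units by
  default (`zscore_kinematics=True` standardises complexity). Enjoyment,
  complexity and recognition are modelled jointly in one regression;
  there is no separate-fits mode because the joint fit nests it.

**Priors** (all configurable): Normal(0, 10²) on slope coefficients,
Normal(0, 20²) on the intercept, half-Student-t(3, 0, 10) on the
residual and random-intercept SDs. On the 0–100 error scale these are
weakly informative: they admit implausibly large effects and let the
data dominate.

**Posterior summaries.** 95% highest-posterior-density intervals,
computed as the shortest window over the sorted draws (tested against an
exhaustive scan and against `arviz.hdi`). An effect is *substantial*
when its HPD excludes zero, and a *trend* when the HPD overlaps zero but
less than 10% of posterior mass lies on the minority side.

## The sampler

The Gaussian random-intercept model is conjugate given its variance
parameters, so the sampler is a blocked Gibbs scheme with no tuning:

1. σ² and τ² are slice-sampled (log scale, stepping-out) from their
   conditional with **both** the coefficients β and the random
   intercepts u integrated out. The marginal likelihood is closed-form
   through the precomputed Gram matrices of W = [X Z]. Marginalising the
   coefficients matters: several predictors (traits, recognition rate)
   vary only at the participant level and are posteriorly entangled with
   the random intercepts, which makes naive alternating Gibbs mix slowly
   on exactly these models. The half-t prior density is used directly in
   the slice target (its inverse-gamma mixture representation was tried
   and is itself slow-mixing).
2. (β, u) are then drawn exactly from their joint Gaussian conditional.

Successive draws are close to independent; split-R̂ across chains
(default 4 chains × 1000 draws after 1000 warmup) is computed for every
parameter, and R̂ > 1.01 raises a `ConvergenceError` naming the
offenders. Chains use independently spawned generator streams from one
seed; results are bit-reproducible.

## fNIRS chain

Stages, in order, for long channels (20–40 mm source–detector
separation; short channels < 20 mm serve only as nuisance regressors;
no channel is ever excluded on quality grounds — the scalp coupling
index, the cardiac-band correlation between the two wavelengths, is
reported for inspection only):

1. **Optical density**: OD(t) = −ln(I(t)/Ī), natural-log convention,
   baseline = whole-recording mean intensity (configurable). Any
   baseline choice only shifts OD by a constant, which the GLM constant
   absorbs.
2. **TDDR** motion correction: the signal is split at 0.5 Hz; the
   low band's temporal derivative is robust-reweighted (iterated Tukey
   biweight, tuning constant 4.685 × a MAD-based robust SD, iterated to
   weight convergence, max Δweight < 1e−6 or 50 iterations),
   re-integrated, and recombined with the high band. The implementation
   agrees with the published reference implementation to ~1e-10.
   Two practical notes, both verified against that reference: at 2.6 Hz
   a single-sample spike is only partially suppressed (its high-band
   residue passes through by design), and on *noise-free* simulations
   the derivative MAD collapses so the biweight rejects genuine response
   ramps — hence the noise-free round-trip validation runs with TDDR
   disabled, and the TDDR tests use realistic background noise.
3. **Modified Beer–Lambert law**: per time point the 2×2 system
   OD_λ = ln(10)·ε_λ,X·C_X·d·PPF is solved for (HbO, HbR), with decadic
   Gratzer/Cope-lineage extinction coefficients at 760/850 nm shipped as
   a versioned CSV, optode distance d in cm, and PPF = DPF/PVC = 6/60
   = 0.1 by default. The ln(10) factor reconciles the natural-log OD
   with base-10 extinction units; the simulator's forward model and this
   inverse are exact mutual inverses (round-trip error < 1e−8 in
   concentration units, machine precision in practice).
4. **GLM**: one regressor per condition — a 16-s boxcar at each event
   onset convolved with the canonical double-gamma HRF (gamma peaks at
   6 s and 16 s, undershoot ratio 1/6), built on a 10× oversampled grid
   and scaled to unit single-event peak so betas read as response
   amplitudes; a discrete-cosine drift basis with frequencies ≤ 0.01 Hz;
   the leading principal components of the short-channel HbO/HbR
   signals, retained to 95% cumulative variance (count overridable); and
   a constant. Fitting is OLS followed by Cochrane–Orcutt AR(1)
   prewhitening (ρ from the lag-1 residual autocorrelation; ρ is set to
   0 when residuals are pure float round-off, as on noise-free
   channels), with standard errors from the prewhitened fit.
5. **ROI aggregation**: inverse-variance weights 1/SE² by default
   (β_ROI = Σwβ/Σw, SE_ROI = √(1/Σw)); "weighted by the standard error"
   admits a 1/SE reading, which is available as
   `weighting="inverse_se"`. Twelve ROIs: {L,R} × {IFG, MFG, PMC, MC,
   STG, IPL}.
6. **HbO−HbR difference** per participant × ROI × condition, with the
   sign rule: canonical (HbO > 0 > HbR), inverted (HbO < 0 < HbR), else
   same-sign (possibly blood-pressure/extracerebral in origin).
   Same-sign estimates are retained by default.

## Brain–behaviour models

`HbDiff ~ 1 + condition × ROI × error + recognition_rate +
mean_enjoyment + (1|ID)`, one record per participant × ROI × condition,
where `error` is the participant's mean estimation error per condition
(it is crossed with condition), recognition rate is the proportion of
correct performed/unknown judgements, and continuous predictors are
z-scored across the records. Per-ROI condition slopes, their
condition-aggregated mean and performed-minus-unknown contrast are
linear functionals of the coefficient draws, so the contrast equals the
draw-wise slope difference identically. The moderation variant adds
body-competence main and error×(condition×)body-competence terms and
reports the ROI-averaged error slope at body competence −1 SD, mean,
+1 SD with pairwise differences; at z = 0 the conditional slope reduces
to the main-effect slope by construction.

## Synthetic-data generators

The generators define the study conditions under which everything is
tested:

* **Kinematics**: leader joints follow sums of 3–6 random-phase
  sinusoids below 1 Hz on an anatomical rest pose (trunk nearly still,
  hands most mobile, ~40 px amplitude); the follower replays the leader
  with a lag (default 3 frames), amplitude scale, and additive Gaussian
  coordinate noise. This yields a monotone mapping from noise SD to the
  synchrony score, which the tests exploit. It does not emulate
  occlusion, tracking glitches, or genuinely improvised movement.
* **Schedule**: videos split evenly at random into performed/unknown;
  n/2 blocks of (mirror performed video, then observe that performed
  video and one unknown video in random order); block timing 16 s video,
  4 s post-mirror gap, 8 s rating periods (68 s per block) — invented
  but plausible timing, only the 16-s video length being externally
  fixed.
* **Observer model**: D_iv = intercept_cond + Σβₖz_ik + u_i + ε_iv with
  defaults mirroring the magnitudes reported for this task (intercepts
  14.4/19.1 error units; trait coefficients of order ±2 per SD;
  random-intercept SD 7 and residual SD 15, chosen as plausible for
  0–100 sliders since the study reports no variance components).
  Estimates are clamped to the 0–100 slider. Enjoyment is generated as
  a noisy linear function of −D (intercept 50, unit link, SD 10) —
  a stand-in, as only the fitted association is known, not the
  generative direction; recognition is Bernoulli (hit rate 0.75,
  false-alarm rate 0.25).
* **fNIRS forward model**: per long channel, the ROI's true HbO
  amplitude (defaults 1.0 μM performed / 0.7 μM unknown, HbR = −HbO/3,
  the canonical polarity) multiplies the same unit-peak regressor the
  GLM uses; concentrations go through the forward Beer–Lambert relation
  to decadic OD and I = I₀·10^(−OD). All channels share a superficial
  component (Mayer-wave ≈ 0.095 Hz + cardiac 1.1 Hz + slow noise,
  channel-specific gains, SD 3e-3 OD), plus linear drift (2e-5 OD/s,
  random sign), white intensity noise (5e-4 relative), and optional
  spike/shift artifacts. Short channels carry everything except the
  event-locked response. Real extracerebral physiology is richer
  (heterogeneous superficial topography, respiratory bands, motion
  coupling); passing the round-trip and rejection tests shows the chain
  is self-consistent and removes the simulated nuisance structure, not
  that it handles every real-world confound.

## Problem sizes and numerical choices

Recovery and calibration studies run at the study scale of 43
participants × 40 observation trials, 20 replicates each, with reduced
sampler settings (2 chains × 500 draws after 500 warmup; R̂ bound 1.05
for these replicate fits). The fNIRS validation simulations use 12 long
+ 2–4 short channels over 8-video schedules; the demo pipeline defaults
to 8 videos, 12 observers, 6 fNIRS participants and 24 long channels.
These sizes keep the full validation suite to a few minutes while
leaving all effect sizes, rates and noise levels at their study values.

Degenerate inputs are handled explicitly: all-coincident pose frames
(uniform vector + flag), constant series (SampEn 0), zero-variance
z-scores (error), non-positive intensities (error naming the channel),
rank-deficient designs (error), |ρ| ≥ 1 (error, except the float-noise
case above). HPD ties are broken by the first narrowest window in sort
order.

## Limitations

* Synchrony is strictly frame-simultaneous: no time-lagged or windowed
  cross-correlation variants, no 3-D pose, dyads only.
* The behavioural models are Gaussian; sliders are bounded and the
  clamping at 0/100 is not modelled (ratings near the bounds attenuate
  estimates slightly, visible in the recovery studies' design).
* One random-intercept grouping (participant); no crossed video random
  effects.
* The fNIRS chain is channel-space only: no image reconstruction, no
  HbT, no frequency-domain NIRS; SNIRF ingestion is limited to what the
  montage CSV describes.
* With few participants, participant-level predictors (six traits, or
  recognition + enjoyment + body competence) can exhaust the
  between-participant degrees of freedom; the design-rank check fails
  fast with a clear message rather than fitting an unidentified model.
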