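# Methods

`reachdyn` analyzes planar center-out reaching performed with the arm
supported on a horizontal plane (exoskeleton-style), contrasting a *control*
condition with a reversible *cerebellar block* condition. This note
documents the model, the measures, the statistical layer, and the synthetic
data generator, including the choices made where more than one reasonable
design existed.

## Two-link limb model and torque decomposition

The arm is a planar two-link rigid chain: upper arm (length `l1`) and
forearm+hand (`l2`). The shoulder angle `θs` is measured from the workspace
+x axis; the elbow angle `θe` is internal-relative (0 = fully extended).
Because the arm is supported, there is no gravity term. With composite
inertial coefficients

```
a1 = I1 + I2 + m1 r1² + m2 (l1² + r2²)
a2 = m2 l1 r2
a3 = I2 + m2 r2²
```

the joint torque at each joint is decomposed into

* **net** torque: the own-joint inertial term — `(a1 + 2 a2 cosθe) α_s` at
  the shoulder, `a3 α_e` at the elbow;
* **coupling** (interaction) torque: everything a joint feels because the
  *other* joint moves — the off-diagonal inertial terms plus the
  centripetal/Coriolis velocity products;
* **muscle** torque: net − coupling, identically equal to the generalized
  applied torque of the standard two-link equations of motion. It absorbs
  musculoskeletal (and manipulandum) viscoelastic effects, which are not
  modelled separately.

The split of the velocity-product terms between "net" and "coupling" is a
convention; assigning them all to coupling makes the shoulder coupling
torque exactly zero whenever the elbow is stationary, which matches the
qualitative behavior expected of near-single-joint reaches. Additive
corrections `exo_a1/a2/a3` allow a co-moving exoskeleton linkage to be
folded into the coefficients; they default to zero, which scales but does
not restructure any percent-change analysis.

Inertial parameters are estimated from body mass by proportional
anthropometry: segment mass fractions (defaults 0.03 / 0.025 of body mass),
COM at 0.45 of segment length, gyration radius 0.3 of segment length. The
exact regression used for any particular subject is configurable; all
condition contrasts are ratios and are insensitive to this choice. Validity
is enforced as positive definiteness of the inertia matrix over the full
elbow range, checked by grid scan.

Forward dynamics integrates `M(θ) α + C(θ, ω) = T_m` with fixed-step RK4 at
the sampling interval (1 ms). Torques at RK4 half-steps are interpolated
with a 4-point cubic stencil; with linear interpolation the control input,
not the integrator, limits accuracy (round-trip errors ~5e-6 rad instead of
<1e-7 rad over 0.5 s).

## Preprocessing

Raw kinematics (1 kHz) are low-pass filtered with a zero-phase
forward-backward 2nd-order Butterworth filter (10 Hz cutoff); zero-phase
filtering is used so onset estimates are not delayed. Trials span cue
presentation to peripheral-target entry, so the extracted segment is mostly
the acceleration phase of the reach; all kinetic measures are therefore
defined on that phase. Movement onset is the first sample at which hand
speed exceeds 5% of its trial peak. "Radial hand velocity" is interpreted
as hand speed (the tangential magnitude); the alternative projection onto
the center-to-target radius is available (`preprocess.radial_velocity`) but
is not the default.

## Trial measures

* **Peak hand velocity**: max hand speed over the epoch.
* **Acceleration phase**: onset to the first positive-to-non-positive
  crossing of the hand-speed derivative (the first speed peak), or the end
  of a truncated epoch.
* **Torque impulse**: trapezoidal time-integral of a torque component over
  the acceleration phase, signed. Target-wise normalization divides by the
  maximum absolute target-wise median; change measures reference the
  control-condition maximum, because per-target ratios are unstable when an
  impulse median is near zero.
* **Decomposition index (DI)**: trial time from onset is normalized to
  [0, 1] and split into 1000 bins; a bin counts as decomposed iff exactly
  one joint's absolute angular speed is below 20 °/s (both-below does not
  count). Each bin takes the sample nearest its center; `any`/`all`
  aggregation over in-bin samples is available behind a flag. The index is
  the mean of the bins, hence invariant to uniform time rescaling.
* **Trajectory variability**: each hand path (from onset) is translated to
  start at the origin and rotated so its endpoint lies on the +Y axis; the
  trial's error is the maximum |x| (perpendicular deviation), and
  variability is the sample SD (n−1) of these errors across trials.
* **Velocity matching**: to dissociate speed effects from condition
  effects, control trials are matched to block trials by peak velocity —
  greedy nearest-neighbour without replacement, visiting block trials in
  within-block order, dropping pairs whose relative velocity difference
  exceeds 5%. The matching report (n matched, median |Δv|) makes the
  achieved balance auditable. Greedy matching is a deliberate, simple
  choice; on small examples it agrees with exhaustive optimal assignment.
* **Trial sequences**: trials to one target are ordered by their
  within-block index and given presentation ranks 1..K, binned as early
  (1–2), mid (3–10), late (11–20). With ~50-trial blocks over 8 targets a
  single target's rank cannot reach 11–20, so the *adaptation analysis*
  ranks the pooled high-coupling target group (targets 2–4), whose sequence
  does reach the late bin; per-monkey values are normalized by that monkey's
  early-control median.

## Statistical layer

The unit of analysis is the session. For each (monkey, session, condition,
grouping) cell, trial values are reduced to their median, and condition
effects are expressed as `100 (block − control) / control` (control-max
referenced for torque impulses, as above). Percent changes are modelled as

```
value ~ fixed effects (target, target group, rank bin, trial set, ...)
        + random intercept per monkey
```

fitted by maximum likelihood. Hypotheses are Wald contrasts `w'β` with a t
reference on residual degrees of freedom (`n_obs − rank(X)`) — a
deliberately small-sample-safe choice; type-I calibration of this test at
the study's size is 5.4% over 500 null replicates (and is re-measured by
the acceptance script). Families of post hoc contrasts are
Benjamini-Hochberg corrected. 95% CIs are Wald by default.

Implementation note: `statsmodels` MixedLM estimates the variance
components, but the fixed effects and their covariance are recomputed by
explicit GLS at those components (`V_g = σ²I + τ²11'`). At the common
τ² → 0 boundary the optimizer's own profiled fixed effects can be
inconsistent with the reported components, and its Hessian-based covariance
can fail to be positive definite; the explicit GLS form is immune to both,
and reduces exactly to OLS when τ² = 0. If the ML fit itself fails, OLS
point estimates with method-of-moments components are used.

The association between coupling load and slowing is a partial correlation
controlling for monkey identity (dummy-coded residualization, t reference
on n − 2 − k df): per session and outward target, the control-trial median
net coupling impulse (sum of absolute shoulder and elbow coupling impulses,
normalized per monkey by that monkey's across-trial median) against the
velocity *reduction*, so a positive ρ means high-coupling directions slow
down more under block.

## Synthetic experiment generator

The generator reproduces the study's data structure: 4 subjects (body mass
4.5–8 kg with per-subject segment lengths), ~10 sessions each, 3–4
sub-sessions per session, each sub-session one block of 80 control trials
followed by 50 block trials, 8 targets at 45° spacing 4.5 cm from a central
start, 1 kHz sampling, ~0.4 s nominal reach duration, and interleaved
return-to-center movements. Target 1 lies along the tangent of the shoulder
circle at the central posture, making it a near-single-joint (low-coupling)
shoulder reach; stepping clockwise makes targets 2–4 demand combined
shoulder–elbow motion. The within-block target order is balanced
pseudorandom (counts differ by ≤1). Randomness derives from per-trial
substreams spawned deterministically from (seed, monkey, session, block,
trial), so any subset regenerates identically.

Reaches are minimum-jerk hand paths, converted to joint space by inverse
kinematics with analytic Jacobian derivatives. Block effects are imposed
kinematically so injected sizes are exact by construction:

* **Velocity deficit**: uniform time dilation; peak speed is exactly
  `velocity factor × 15D/(8T)`. Defaults: outward targets 10%, inward 2%,
  return movements 2%, with natural trial-to-trial velocity variability of
  12% (lognormal) — a realistic within-condition spread that also gives the
  velocity-matching step a usable overlap between conditions.
* **Adaptation**: for targets 2–4 the deficit grows with the group's
  presentation rank as `0.10 + 0.05 (1 − exp(−(rank−1)/4))`, i.e. ~10.5%
  over early ranks 1–2, saturating at ~14.8% by ranks 11–20.
* **Decomposition**: with some probability (control 0.35, rising for
  naturally slow trials; block 0.85) one joint's angle profile is frozen
  for a normalized duration (control 0.06–0.14, block 0.10–0.20) starting
  at 0.55–0.75 of the movement; the other joint completes on schedule and
  holds, extending the trial. Because desynchronizing the joints can expose
  hand-velocity components that cancel in the synchronized reach, a paused
  trial whose peak speed exceeds its unpaused counterpart is uniformly
  re-dilated until the peak-velocity contract holds again — pauses survive
  this exactly (they are plateaus under monotone re-sampling). Slower
  control trials pausing more reproduces, by construction, the empirical
  pattern that velocity-matched (slower) control subsets are more
  decomposed than all controls.
* **Trajectory noise**: a lateral half-sine perturbation with Gaussian
  amplitude (SD 2.5 mm at unit velocity factor, scaled by the square root
  of the velocity factor as a mild speed–accuracy tradeoff) and a ×1.35
  amplitude multiplier under block. Because variability is compared between
  velocity-matched sets, the recovered block/control variability ratio
  tracks the injected multiplier.
* **Success**: Bernoulli flags at 86.5% (control) and 75.3% (block),
  independent of the kinematics.

What the generator does **not** emulate: feedback corrections and
online corrections to perturbations, sensor noise and filtering artifacts,
endpoint-accuracy structure (trials always terminate on the target),
co-contraction or torque-level noise, and any neural mechanism of the
block. Passing recovery tests therefore demonstrates that the *analysis
chain* is unbiased and calibrated for effects of the injected kind and
size — not that these effects are the correct physiological account of
real data.

A consequence of counting threshold crossings is that the end-to-end DI
increase under the default injection (~+80% at the study size, as computed
by the acceptance script) exceeds the nominal pause-budget ratio (+50%):
the movement tails and the pause end-hold also contribute bins. The
matched-control contrast — the scientifically meaningful comparison — is
unaffected.

## Numerical and degenerate-input policy

Reachability outside the annulus `[|l1−l2|, l1+l2]`, non-positive masses or
lengths, unordered event times, empty trial sets, all-zero speed traces,
all-zero normalization references, sub-2-trial variability sets and
mismatched contrast lengths all raise typed errors naming the offending
input. Velocity matching returns an empty, flagged result rather than
raising. Forward dynamics refuses near-singular inertia matrices
(det < 1e-12). The two-solution IK ambiguity is fixed by `elbow_sign`
(+1 by default, matching the generator's posture).

## Problem sizes

Default study size everywhere (tests, acceptance script): 4 monkeys × 10
sessions, ~35k trials, which the full pipeline processes in well under a
minute; the type-I calibration refits the mixed model on 1000 resimulated
summary tables. These sizes give sampling error comfortably inside every
tolerance used by the test suite.

## Known limitations

* The decomposition raster's 20 °/s threshold interacts with the target
  geometry: directions that are intrinsically near-single-joint (target 1,
  and to a lesser degree target 4's shoulder component) carry high baseline
  DI, which is why the DI analyses are restricted to targets 2–4.
* With 4 subjects the monkey-level random intercept is weakly identified;
  the GLS covariance treats the estimated variance components as known,
  which is slightly anticonservative, offset by the t reference.
* The mixed model treats session-level medians as independent given the
  monkey intercept; within-session correlation across targets is not
  modelled.
* Return movements reuse the reach generator with their own deficit; real
  return kinematics (un-cued, often faster and more variable) are only
  loosely emulated.
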