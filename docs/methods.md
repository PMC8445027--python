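# Methods

## The analysis problem

Seven sensory interest points (SIPs) are tracked in a 2D scene: s0–s2 on a
lower arm (s0 the end effector), s3–s5 on an upper arm (s3 the end
effector), s6 at the center of a ball that can only slide along a
horizontal rail.  Each SIP streams its position and a simulated haptic
value; six motors (m0–m2 lower, m3–m5 upper; m2/m5 the base joints) stream
joint commands.  From these streams alone the package answers:

1. which SIPs move together (self vs. other) — velocity correlation;
2. which SIPs an agent controls — motor-to-velocity correlation;
3. which SIPs are autonomous vs. passive — directed acceleration transfer.

## Derived signals

Velocities are backward differences of positions divided by dt, and
accelerations backward differences of velocities, with first-sample padding
so every derived series stays step-aligned with the positions (length T).
Derivatives are invalidated across episode resets: the teleport of ball and
arms back to the start pose is not motion.  Magnitudes are normalized by
the dataset-wide maximum (not per episode), keeping cross-episode
comparability for the pairwise matrices; an all-zero channel keeps scale 1.

The dependency measures operate by default on the **signed speed
derivative** d‖v‖/dt per SIP rather than on the acceleration x component.
The two agree for motion in the +x direction, but an arm pushing in −x
decelerates *from negative velocity*: its a_x is positive while the ball's
kick a_x is negative, and the signed subtraction then reads the transfer
backwards.  d‖v‖/dt is invariant to the direction of travel — "slowing
down" is always negative — which is the quantity the transfer logic is
actually about.  The x/y/magnitude channels remain available
(`accel_channels("x")` etc.).

## Acceleration transfer

Per step, T(a_i, a_j) = a_j − a_i (positive: transfer i → j), with three
filters applied in the order gate → scale → clamp for the full version 4:

* **v3 gate**: keep only opposite-sign pairs, via
  |a_i| + |a_j| ≥ |a_i + a_j| + ε with ε = 0.01 on the normalized scale.
  ε doubles as a noise floor: jitter below ε/2 per channel cannot fire.
* **v2 scale**: multiply by min{1, |a_i|/|a_j|}; defined as 0 when
  a_j = 0.  A silent source transfers nothing.
* **v1 clamp**: |T| ≤ min(|a_i|, |a_j|).  A transfer cannot exceed the
  smaller signal.

The composition order is a design choice (the three filters are described
as successive refinements, not a pipeline): gating first avoids scaling
values that will be zeroed, and clamping last keeps the v1 bound a hard
invariant of the final measure.  Version 0 is antisymmetric by
construction; the filtered versions are not, and nothing in the package
assumes they are.  Matrix aggregation sums signed per-step values by
default, with a rectified (positive-part) option.

## Simulator

The arms are velocity-controlled kinematic chains — a command is a per-step
joint angle change, clipped to 0.05 rad/step and scaled by a per-joint
profile (distal 1.0, elbow 0.3, base 0.45); joints are clamped to ±1.2 rad
(times the same profile) around the start pose.  The profile and limits
mirror a real arm (a wrist is faster and freer than a shoulder) and are
what produces the proximo-distal correlation ordering
corr(v0x, v1x) < corr(v1x, v2x): the slow elbow makes neighbouring inner
SIPs share more of their motion than the distal pair does.

Contact between an arm capsule (half-width 0.05) and the ball (radius
0.12) resolves as follows:

* **Launch**: when the contact normal has |n_x| > 0.2 and the contact point
  is catching up with the ball along the push direction, the ball takes a
  1D elastic bounce off the (comparatively heavy) arm with restitution
  0.8 — a push is a clean tap that sends the ball away faster than the
  striking point, not a grind.
* **Drag**: any other touch couples the ball toward the rubbing point's x
  velocity with coefficient 0.3 per step — a touch always transfers a
  little momentum, which keeps haptic ground truth and momentum-based
  measures commensurable.
* **Recoil**: an arm that just transferred momentum (|Δv| > 0.05) loses 60%
  of its joint speed on the *same* step — a crude Newton's third law.  The
  alignment matters: the pusher's deceleration and the ball's kick must
  land on the same instant for an instantaneous measure to see the
  exchange.  Recoil releases fully on the next step; a slow deterministic
  recovery ramp would make the arm's future predictable from the ball's
  kick and invert net transfer entropy.
* Penetration relaxes gradually (30% per step); a hard positional snap
  reads as a spurious reversal once differentiated.

The rail is low-friction (0.5% velocity loss per step): a launched ball
coasts.  With strong friction the ball's steady deceleration pairs against
any jittering channel and accumulates a continuous false "transfer out of
the ball", which would break the sink signature.  The ball resets to the
middle (and the arms to the start pose) whenever it slides past a box edge.

Reported SIP positions carry Gaussian observation noise (sd 0.001 world
units, ~0.03% of the workspace), emulating visual feature-extraction
jitter; dynamics and haptics use true geometry.  Haptics are proximity
based — h = max(0, 1 − d/0.5) to the nearest contact point — and are felt
only by the bodies involved in the contact.

### Policies

Seven controllers: `static` (nothing), `babbling` (per-joint velocities
drawn uniformly and held for 10–40 steps, independently per arm — shared
randomness would fake an inter-arm correlation), `goal_directed`
(proportional servoing of the tip toward the ball, gain 3),
`constant_push` (saturated activation toward a point 0.4 units *through*
the ball along the tip-to-ball line — aiming at the ball itself makes the
controller ease off before impact, and a hard sign rule chatters),
`staggered_push` (constant push gated on/off with probability 0.5 per
10-step block), `random_push` (push direction, magnitude uniform in [0, 1]
per block), `random` (per-joint activations uniform in [−1, 1] per block).

### Dataset recipes

* `babbling`: one long episode, both arms babbling independently — the
  input of the correlation analysis (10,000 steps in the test suite; the
  structure is stable from a few thousand steps).
* `at_repetitions`: N short episodes (300 steps), one arm goal-directed and
  the other babbling, roles chosen with probability 0.5 per episode — the
  input of the AT/GC/TE matrices and the sink analysis.

## Baselines

Granger causality compares nested autoregressions (restricted: the target's
own `lag` lags; full: plus the source's lags) with an F-test on the added
coefficients; lag defaults to 5, kept small because the trials are short.
The stationarity precondition can be checked with the augmented
Dickey–Fuller test (`check_stationarity`); the simulator's derived channels
pass it.

Transfer entropy is the histogram estimator of
H(y_t | y_past) − H(y_t | y_past, x_past) in bits, with equal-width bins
(default 8) and history 1, and a Miller–Madow bias correction on by
default: the raw plug-in's mean bias at these settings and n = 10,000 is
itself ≈ 0.02 bits, so independent series would otherwise score a spurious
positive transfer.  Corrected values may dip slightly below zero.
Dataset-level matrices report the fraction of episodes passing GC at
p < 0.05 and the mean TE in bits; both are asymmetric and never
symmetrized.

## Graphs

For an asymmetric measure matrix, edge i → j is kept when the net weight
w_ij − w_ji exceeds θ = 0.1 × max|entry| ("significant" transfer is not
otherwise definable without a null model; an episode-shuffle surrogate
threshold is provided as an option).  Sinks — no outgoing kept edge, at
least one incoming — are labeled `passive`; isolated nodes `unresolved`;
everything else `autonomous`.  For the symmetric correlation matrix,
|ρ| ≥ 0.3 thresholding plus connected components realizes "what moves
together clusters together"; undefined correlations (zero variance — e.g.
an untouched ball) carry a NaN sentinel and contribute no edge.

## Benchmark

Seven scenarios pair the policies (constant/staggered/random push, random,
static) with roles alternating between the arms each trial; 100 trials of
300 steps per scenario.  Ground truth is haptic co-contact at arm
granularity: all three SIPs of an arm are positive iff that arm and the
ball registered haptics ≥ 0.1 at the same step.  Binarization:

* **AT**: net version-4 transfer toward the object above 5% of the trial's
  strongest pair (gross |T| sum).  The fraction was fixed on scenario-1
  validation seeds and then frozen.
* **GC**: p < 0.05 on the arm-SIP → object test; undefined tests (constant
  channels) count as negative.
* **TE**: net TE toward the object above the 95th percentile of 20
  time-shuffled surrogates.  For this trial-level use the channels are
  rank-transformed before binning (equal-frequency bins) with 12 bins:
  contact impulses make the raw signals so heavy-tailed that equal-width
  bins starve the estimator.
* If the observed ball displacement never exceeded 10× the observation
  noise sd, the trial carries no causal information about the object and
  every measure reports all-negative.

Scores are pooled (micro) F1 over all trials of a scenario:
2TP / (2TP + FP + FN).

## What the synthetic world does and does not show

The generator reproduces the *causal structure* the measures depend on —
only contact moves the ball, the pusher loses what the ball gains, haptics
mark true contacts — and the qualitative phenomena: proximo-distal
correlation ordering, sign-split motor maps between the two arms, the
object as the unique AT sink, AT's false-positive mode on opposite-signed
random signals, and AT ≥ GC with TE in between on the benchmark.  It does
not reproduce any particular physics engine: torque-level dynamics,
arm–arm collisions, 3D effects and real visual front-ends are absent, and
absolute F1 cells depend on contact-model constants that have no canonical
values.  Numbers produced here are therefore comparable in pattern, not in
third decimal, to any other implementation of the same design.  One known
deviation: AT performance across scenarios 1–4 spreads by ~0.2 here
(scenario 4's random arm touches the ball mostly in weak grazes) rather
than being flat.

## Degenerate inputs and numerical choices

Pearson correlation returns a NaN sentinel (never silent 0) when a variance
is zero; conditioned matrices require ≥ 3 masked samples.  Series shorter
than 3 steps, even smoothing windows, non-finite accelerations, lag ≥
length, and constant series for GC/ADF all raise.  Constant series give TE
0 with a warning.  All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (per-arm policy streams, per-trial
episode seeds, TE surrogate streams); identical seeds reproduce every
artifact byte for byte.
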