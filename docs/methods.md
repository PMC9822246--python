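# Methods

## The crawl/turn/pause model

A simulated larva is a point agent in a rectangular arena (default
240 × 240 mm) with rigid boundaries. Time advances in steps of Δt = 0.5 s
(2 frames/s, matching the tracker frame rate); a 50-minute experiment is
6000 steps. At every step one of three mutually exclusive motor states is
drawn with constant probabilities: turn with P_turn·Δt, pause with
P_pause·Δt, crawl otherwise. Per-step probabilities scale linearly with Δt
(not 1 − exp(−rate·Δt)); at the shipped rates (≤ 0.25/s) the difference is
below 7% and linear scaling makes the expected ground-truth turn count
exactly 60·P_turn per minute, which the self-consistency tests rely on.

* **Crawl** advances the position by heading · v · Δt with v drawn fresh
  each step from 𝒩(μ_v, σ_v) truncated to v > 0 by resampling. Speed is
  memoryless between steps; nothing in the motor tables constrains
  within-bout persistence, and the memoryless reading is the simplest.
* **Turn** rotates the heading by a von Mises(μ, κ) angle and carries no
  translation that step.
* **Pause** freezes position and heading.

Motor parameters are looked up under the larva's current position each
step, so crossing a patch border switches the parameter set the following
step. The packaged tables (`larvaforage/data/*.yaml`) hold the measured
(genotype, substrate) parameters: the homogeneous-substrate table drives
the predictive model, and a second, "corrected" table measured inside and
outside patches in patchy arenas is shipped as an alternative set.

**Boundaries.** A crawl step that would exit the arena is truncated at the
wall and the heading is re-sampled uniformly into the interior. The
alternative (specular reflection) makes no measurable difference to
residence fractions at these speeds but can visibly stick agents to walls
when the incident angle is shallow; the uniform re-draw avoids that
artifact.

**Initial conditions.** Runs start uniformly inside a uniformly chosen
patch (matching the experimental protocol of placing larvae on food), with
heading uniform on the circle; homogeneous runs start at a given point or
uniformly in the arena.

## Turning individuality

Each larva carries its own von Mises turning-angle model. The per-larva
distributions fitted to recorded larvae are not published, so the default
stand-in draws μ once per larva from U(−0.3, 0.3) rad (individual
CW/CCW handedness) with κ = 1; both are configurable
(`residence_ensemble(mu_half_range=…, kappa=…)`).

This stand-in is the model's main source of quantitative uncertainty.
Patch residence on yeast is sensitive to the turning-angle distribution:
sweeping κ over [0, 2] and the μ half-range over [0.3, 1.0] moves
rover–yeast residence between roughly 16% and 20%, while a reversal-heavy
model (large fixed |μ|) pushes it above 22%. Real larval turning angles
measured by RDP are large — tens of degrees up to reversals — so the
small-angle stand-in under-confines larvae in slow, pause-rich patches.
Sucrose and agar-control residence is insensitive to this choice because
motor parameters inside and outside differ little there.

## Inward-turn bias

After a turning magnitude |θ| is drawn, the two candidate post-turn
headings (rotation by ±|θ|) are compared by the angle their movement
vectors make with u⃗ = P⃗ − p⃗₁, the vector from the turn location p⃗₁ to
the nearest patch center P⃗. With probability Pbias(d) the candidate with
the smaller angle (the inward option) is chosen, otherwise the other one;
beyond the 60 mm cutoff — or exactly at a patch center, where u⃗
degenerates — the originally signed draw is used unchanged. Under this
construction the realized inward fraction at distance d equals Pbias(d),
which is how bias profiles are measured from data, so user-supplied
experimental profiles plug in without transformation. Bias probabilities
are distance-binned (half-open bins); the packaged
`bias_example.yaml` is a synthetic illustration, not measured data.

**Fragmentation.** The reference food area S = 2π·25² mm² (two 25 mm
patches) redistributed over N patches gives radius R′ = √(S/(Nπ)); patch
centers are placed by rejection sampling (≤ 10,000 attempts per patch,
non-overlapping, fully inside the arena). Bias-profile bin edges and
cutoff are multiplied by R′/R so the bias acts on the same relative
geometry around smaller patches.

## Trajectory analysis

* **Smoothing.** A constant-velocity linear-Gaussian Kalman filter on the
  (x, y) centroid, state (x, y, vx, vy), isotropic white-acceleration
  process noise (default σ = 0.05 mm/s²) and measurement noise (default
  σ = 0.1 mm, matching the synthetic generator's default jitter). The
  filter is forward-only by default; a Rauch–Tung–Striebel backward pass is
  available (`rts=True`). The state is initialized at the first
  measurement with zero velocity and loose velocity covariance.
* **Kinematics.** Backward differences: V⃗(t_j) = (R⃗(t_j) − R⃗(t_{j−1}))/Δt,
  speed ‖V⃗‖, unit heading, and turn rate arccos(H⃗(t_{j−1})·H⃗(t_j))/Δt with
  the arccos argument clamped to [−1, 1]. The first frame carries no
  velocity. Zero-displacement frames have no heading; they are flagged,
  their turn rate is reported as 0, and the last defined heading is
  propagated across them so the next moving frame gets a meaningful turn
  rate.
* **Turn detection.** Standard RDP (iterative, so recursion depth cannot
  overflow on long smooth arcs) with perpendicular point-to-chord-line
  distance, falling back to point distance for degenerate chords. ε
  defaults are keyed by substrate: 2.5 mm for agar/sucrose/apple juice,
  1.25 mm for yeast (slower, tighter tracks). Interior vertices are the
  turning points; the signed angle at each is atan2(cross, dot) of the
  adjacent segment vectors, CCW positive. Angles of exactly 0 count as
  neither CW nor CCW in the handedness score.
* **Inward/outward.** θ₁ and θ₂ are the angles of the incoming and
  outgoing segments with u⃗; inward iff θ₂ < θ₁. Exact ties (within 1e-12,
  e.g. a perfectly radial exit) are labelled outward — the conservative
  choice, declared rather than inferred, since perfectly radial geometry
  has no inward option. Degenerate zero-length segments are
  unclassifiable. Inward fractions are tabulated in half-open 10-mm bins
  up to 60 mm; farther events are excluded (data beyond that range are too
  sparse to bin).
* **Turns per minute.** A binary per-frame indicator marks RDP interior
  vertices; overlapping 120-frame (1 min) rolling windows are summed and
  the window sums averaged.
* **Residence metrics.** "Inside" is a per-frame closed-disc test on the
  centroid with no border hysteresis. Fraction of visited patches discounts
  the source patch: distinct others entered / (N_p − 1). Pause detection on
  recorded-style tracks uses a speed threshold (default 0.1 mm/s, one
  frame) because tracker data carry no state labels; for simulated runs the
  ground-truth state log is authoritative. Per-larva metrics average with
  equal weight per larva, then per run.

## Synthetic recordings

The study's raw videos are not deposited, so tests run on generated
tracker-style tracks with complete ground truth. The generator builds
piecewise-ballistic paths — crawl bouts with one speed per bout,
instantaneous heading changes at turns, frozen pauses — and adds isotropic
Gaussian centroid jitter post hoc (default sd 0.1 mm), modelling
measurement noise only; jitter never feeds back into the dynamics. A
deterministic variant builds a track from an explicit turn schedule, which
makes exact round-trip tests possible: at zero jitter RDP recovers the
scheduled corners to the frame and the angles to 1e-9.

What the synthetic tracks do **not** emulate: posture and head-cast
dynamics (centroids only), tracker identity swaps and dropouts, border
crawling artifacts on real food edges, and any odor-driven modulation.
Passing round-trip tests therefore shows the analysis chain is correct on
clean centroid data, not that it is robust to every tracker failure mode.

## Problem sizes and determinism

The residence experiments average 30 larvae × 30 runs × 6000 steps per
condition, the design of the original simulations; trend checks
(bias uplift, fragmentation N = 1 → 8 → 64, yeast > sucrose) use 15 larvae
× 6 runs, enough for the effects, which are several-fold, to dominate
Monte-Carlo noise. All randomness flows from `numpy` `SeedSequence`
spawning: one child per larva, one grandchild per run, so every result is
bit-reproducible for a fixed seed and larvae are statistically independent.

## Known limitations

* Per-larva turning-angle distributions are a declared stand-in (see
  above); absolute yeast residence is a few percentage points below the
  published simulations for that reason, while sucrose and agar controls
  match.
* The exact two-patch center coordinates of the experimental arenas are
  not published; the default places them 120 mm apart on the arena
  midline (configurable).
* Linear per-step probability scaling assumes P·Δt ≪ 1; it is validated
  for the shipped tables but misbehaves if users supply rates near 2/s.
* No feeding, energetics, olfaction, inter-larva interaction, or
  internal-state dynamics: larvae are independent memoryless agents.
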