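# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic-data validation does and does not show.

## Coordinates, units, screens

All analysis runs in degrees of visual angle, screen-centered, x rightward
and y upward. Stimulus parameters are specified in pixels of a concrete
display; two presets are shipped (`necker`: 40 cm / 1024 px at 57 cm,
0.0393 deg/pix; `replication`: 36 cm / 1280 px at 57 cm, 0.0281 deg/pix)
and the small-angle conversion is applied once at generation. Published
pixel values are taken as authoritative where printed degree equivalents
are internally inconsistent. Intervals are 0-based half-open sample
indices; human-facing table columns are seconds.

## Stimulus generators

* **FX** — target fixed at the screen center.
* **RW** — one step per 75 Hz frame; step length ϱ = G + E with
  G ~ Normal(1.1, 0.2) pix and E exponential with parameter 0.1, step
  direction uniform on (−π, π]. The exponential parameter is read as the
  *scale* (mean 0.1 pix): the rate reading implies an 11-pix mean step
  inside the 10-pix arena, contradicting the slow-motion regime; both
  readings are selectable. A step that would exit the 10-pix disk is
  reflected through the center and, if still outside, radially clipped to
  the boundary — every emitted sample satisfies ‖q‖ ≤ 10 pix.
* **LJ** — x = A sin(cθt), y = B sin(dθt + φ) with A = B = 14 pix, φ = 0,
  (c, d) uniform over {(2,3), (3,2), (−2,3), (−3,2)} per trial, and
  θ = 2π·30/(2.21·415) ≈ 0.2055 rad/s by default (a 0.2·2π rad/s preset is
  also provided). At this θ a 34-s trial holds only ~2–3 cycles per axis,
  which matters for the MPC null (below).
* **Luminance schedule** — five levels {0.30 … 0.70} of white, each new
  level uniform over the other four, hold durations log-normal(μ=1, σ=1) s.
* **Trial durations** — fixed 34 s for the replication designs; the
  variable-duration design ended trials on a perception-dependent stopping
  rule that cannot be simulated without a perception model, so durations
  are drawn from a truncated normal (mean 34 s, sd 13.26 s, min 2 s)
  matching the reported moments.

Under these parameters the RW ensemble's screen inertia settles near
0.07 deg² against the LJ figure's 0.30 deg² — the same order of magnitude
(the balancing claim asserted loosely in the tests) but not equal.

## Gaze simulator

Gaze is a unit-mass particle in a softened-gravity potential
V(q,t) = −Σᵢ mᵢ(t)/√(‖q−aᵢ(t)‖² + εᵢ²), integrated by Euler–Maruyama:
dq = v dt, dv = (−∇V − γv) dt + σ_n dW (an overdamped first-order variant
is available; the inertial particle is the default since the noise enters
the velocity). Near a core the potential is quadratic with stiffness
m/ε³, so masses are set through the natural frequency ω₀ = √(m/ε³) with
ε = 0.3 deg throughout.

Calibrated defaults (frozen by `scripts/calibrate_simulator.py`):
γ = 14 s⁻¹, σ_n = 4.2 deg·s^−3/2, dt = 1 ms (matching the 1000 Hz
recording rate), escape radius 20 deg. Under the pure-fixation
configuration (static center attractor, ω₀ = 12 rad/s) the 95th-percentile
drift speed is 1.9 deg/s, inside the < 2 deg/s fixational regime. The
tracking designs weight a target-riding attractor at ω₀ = 10 rad/s against
a weak ω₀ = 1 center (`necker_like`, `cross_like`); the fixation-dominated
design inverts this (ω₀ = 0.3 target vs ω₀ = 12 center, `square_like`).

Micro-saccades are injected kinematically rather than emerging from the
potential: ballistic minimum-jerk (or triangular) displacements with peak
velocity = slope × amplitude (slope 60 s⁻¹ by default, hence ~31 ms
events), Poisson-like timing, and mostly *corrective* aim — each event
points back along the accumulated injected offset with amplitude matched
to it (clipped to the admissible range), so the offset process resets at
roughly the inter-saccade interval. Exact ground-truth event lists are
returned for detector validation. Cohorts are idiosyncratic: each subject
draws a log-normal noise multiplier (cv 0.3) and a saccade rate uniform in
1.5–2.5 Hz.

Two calibration facts shaped these choices. First, MPC between an
*independent* smooth gaze and the few-cycle Lissajous stimulus is more
positively skewed than against the random walk (a small-sample
maximization effect the similarity analysis must live with); slow gaze
components — in particular a slowly wandering saccade-offset process —
inflate that skew, and the fast corrective saccade regime plus the stiff
fixation attractor keep the zero-coupling null shift near +0.01, well
below the per-subject sampling noise of condition medians (~0.05). Second,
the velocity-domain MPC of simulated tracking is much lower (~0.2 for the
Lissajous condition) than position-domain MPC, because the simulated drift
velocity noise in the 0–35 Hz band is large relative to the sub-deg/s
stimulus velocities; real drift is smoother in this band. Velocity-mode
MPC is therefore exercised for correctness but not used in the qualitative
cohort properties.

What passing the cohort tests shows: the full chain (simulation →
filtering → parsing → detection → metrics → permutation statistics)
reproduces the qualitative dissociation — near-unanimous, significant
LJ-over-RW similarity under explicit tracking; no significant contrast
under fixation dominance. What it does not show: agreement with human
micro-pursuit magnitudes beyond order-of-magnitude realism, emergent
catch-up saccades, perceptual reversals, or tracker artifacts (the
pupil-deformation correction is a pass-through hook).

## Preprocessing

Second-order Butterworth low-pass at 35 Hz applied forward–backward
(`sosfiltfilt`), so the cutoff gain is the squared −3 dB point (1/2) and
the phase is exactly zero — phase lag would bias sample-by-sample
gaze–stimulus comparison. Masked samples are linearly interpolated before
filtering and re-masked after. Downsampling from 1000 to 75 Hz (a
non-integer ratio) is by linear interpolation onto the uniform frame grid
starting at t₀; a new sample is masked if either bracketing source sample
is. Fixation parsing applies EyeLink-style absolute thresholds on the
guiding eye (speed > 30 deg/s or acceleration > 9500 deg/s², with
candidate saccade runs honored only if their net displacement exceeds
0.15 deg); complementary runs become fixations. Screening removes, in
priority order: epochs ≤ 80 ms (strict), epochs containing missing
samples, epochs whose `I_screen` is beyond mean ± 2 SD of the batch
(statistics computed once per experiment × condition, single pass).

## Micro-saccade detection

Velocities from the 5-point stencil v_i = (q_{i+2}+q_{i+1}−q_{i−1}−q_{i−2})
/(6Δt); per-axis noise scale σ_a = √(median(v_a²) − median(v_a)²);
elliptic criterion (v_x/λσ_x)² + (v_y/λσ_y)² > 1 with λ = 6; runs of at
least 3 samples become events. Because the criterion crosses threshold
well after a slowly accelerating onset, runs are extended outward to the
nearest local minimum of the criterion above a 0.2 floor, which removes
the onset bias (validated to ≤ 5 ms against injected ground truth).
Detection runs on the native 1000 Hz signal when available (75 Hz leaves
1–2 samples per event); a binocular coincidence criterion (≥ 1 overlapping
sample in the other eye) suppresses monocular artifacts. Amplitude is the
start-to-end displacement; peak velocity comes from the detection velocity
series. Under the calibrated drift regime the residual false-alarm rate is
~0.03 Hz (Gaussian velocity tails crossing 6×robust-σ ≈ 4σ): the shared
gaze noise of the two simulated eyes means the binocular criterion cannot
remove these, unlike independent instrument noise in real trackers.

## Metrics

Inertia excludes masked samples from both the sum and N (pairwise with the
stimulus path). MPC uses 1/N covariance blocks (the ratio is unaffected by
the 1/N vs 1/(N−1) choice); since ρ(w) = ρ(−w), the signed maximum is
searched over α ∈ [0, π) on a 3600-point grid refined by golden-section
(80 iterations within one grid cell) — the denominator's geometric-mean
structure is not a Rayleigh quotient, so no eigendecomposition shortcut
applies; a ≥ 10⁶-angle brute-force scan is the test oracle (agreement to
1e-9). The signed maximum is primary (it reaches −1 exactly for
point-reflected motion); an |ρ|-maximizing mode is available. Directions
where either signal's projected variance falls below 1e-7 of its trace are
inadmissible — the relative threshold preserves scale invariance, and the
floor keeps the computed correlation reliable to ~1e-9 (rounding error
grows as 1/u for a direction carrying a variance fraction u). When no
direction is admissible (static stimulus) the result is an undefined
marker, not an exception. Epochs need ≥ 7 valid samples (80 ms at 75 Hz).
Velocity-mode MPC first differentiates both signals with the 6-sample
regression slope (the saccade detector instead uses the 5-point stencil);
binocular similarity is MPC of the guiding eye against the other eye.

## Statistics

All group tests are permutation tests with mid-ranked ties, no continuity
corrections, 10 000 permutations by default, and the add-one estimator
p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm), which never returns 0. The
Friedman χ² is computed for k = 2 contrasts as well, so Kendall
W = χ²/(N(k−1)) applies uniformly (and equals 1 exactly at perfect
concordance for every N, k). Pairwise signed-rank contrasts use the
criterion α/#pairs (0.05/3 ≈ 0.017 for three conditions). Per-subject
analyses use Kruskal–Wallis over the three conditions for inertia and
Mann–Whitney between the two motion conditions for MPC (undefined under
the static condition), with a Bonferroni-corrected significance flag. The
type-I simulations in the tests use 1000 replicates at 499 permutations —
the permutation count affects only the Monte-Carlo granularity of each p,
not the size of the test.

## Problem sizes used in the validation suite

Cohort checks run the full published design sizes (9 × 15 and 10 × 15
subjects × trials, 34-s trials at 1000 Hz). The MPC oracle comparison uses
400 random pairs against 10⁶-angle scans plus 20 000 bounds-only pairs;
the parallel-axis identity is fuzzed over 2000 epochs; detector recovery
uses ten 30-s drift segments (>100 injected events). These sizes were
chosen to give stable statistics while keeping the suite runnable in a few
minutes.

## Known limitations

* The simulator's subjects share one dynamics family; idiosyncrasy is
  limited to noise and saccade-rate multipliers.
* No blink model, no tremor (unresolvable by video-based tracking), no
  pupil-size artifacts; the pupil-correction hook is a pass-through.
* Micro-saccades are injected, not emergent, so catch-up-saccade questions
  cannot be studied with this generator.
* The EyeLink-ASC reader covers a minimal sample/event dialect only;
  binary EDF decoding is out of scope.
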