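# Methods

## The stability model

The walker is treated as an inverted pendulum of length `l` (the mean
vertical distance from the CoM proxy to the lowest hallux sample of the
trial; overridable).  The extrapolated centre of mass is
`XCoM = x + v/ω₀` with `ω₀ = √(g/l)`, `g = 9.81 m/s²`, and the
anteroposterior margin of stability at each foot touchdown is the distance
from XCoM to the leading hallux.  The CoM proxy is a convex combination of
sacrum, mid-trochanter and C7 with default weights 0.5/0.3/0.2; the exact
weighting of reduced-marker CoM models varies across laboratories, so the
weights are configuration, and the defaults are validated against the
generator oracle rather than against any published coefficient set.

**Belt-relative velocity.**  On a treadmill the base of support translates
with the belt, so the CoM velocity entering XCoM is the lab-frame
derivative plus the instantaneous belt speed of the stance side
(`belt_relative: true`, the default; a lab-frame variant is available).
The stance side at a touchdown is the landing foot, and the belt speed is
looked up per event rather than interpolated across the side switch —
during a perturbation the two belts differ by up to 80% of the walking
speed, and interpolating across the switch would corrupt the MoS at
exactly the steps of interest.

**Coordinate convention.**  Right-handed lab frame fixed to the treadmill:
+x anterior (walking direction), +y left, +z up.  Ingest can remap axes.

## Processing chain

1. Marker trajectories (100 Hz) are low-pass filtered with a second-order
   Butterworth at 12 Hz applied forward and backward (zero phase; the two
   passes double the effective order).  Edge transients are suppressed with
   reflective padding of three filter lengths.  Forces are thresholded raw.
2. CoM velocity is obtained by central differences of the filtered
   positions (one-sided at the ends).
3. Touchdown/toe-off come primarily from the vertical belt forces
   (1000 Hz): threshold 50 N, contacts sustained ≥ 20 ms, dropouts shorter
   than 50 ms debounced, crossing times interpolated linearly.  A marker
   fallback uses hallux AP extrema (maximum = touchdown, minimum =
   toe-off); a reconciliation step inserts fallback events only where they
   restore left/right alternation.  The combined marker+force algorithm of
   the original event-detection literature is not reproduced verbatim; this
   two-detector scheme is the package's documented stand-in.
4. Step parameters use instantaneous hallux positions (the only foot
   markers in the reduced set); treadmill step length adds no belt
   integration by default (a belt-corrected variant exists).  CVs use the
   sample SD (n−1).

## Stability-normalized speed

Mean MoS of the final 10 steps per trial is fitted against trial speed
with a second-order polynomial (least squares over the eight speeds
0.4–1.8 m/s); the normalized speed is the root of the fitted curve at the
target MoS (0.05 m) on its decreasing branch within the measured range.
If the quadratic has no usable in-range root the solver falls back to a
linear fit and flags the result as extrapolated when outside the range.
Quadratic order was chosen because curvature of the MoS–speed relation is
visible at the slow end while eight points do not support more; results
are reported to 0.01 m/s.

## Perturbations and recovery

The belt under the perturbed foot accelerates at 3 m/s² to a ceiling of
180% of the baseline speed, starting when the perturbed-side hallux passes
the contralateral hallux in the sagittal plane (mid-swing), holding until
toe-off of the perturbed limb, then decelerating symmetrically.

Steps are labeled relative to each onset: Base = mean MoS of the 11th to
2nd-last pre-onset steps, Pre = the last pre-onset step, Post1–8 the first
eight steps after onset (a touchdown exactly at the onset counts as Post1
— a deterministic tie-break).  The recovery-step count scans backward from
Post8: it is 8 minus the length of the consecutive run of steps, ending at
Post8, within 0.05 m of Base.  Under this reading a late out-of-band step
invalidates earlier in-band ones, and an out-of-band Post8 yields 8.  The
protocol wording admits a variant in which the in-band run may restart;
the backward-scan reading is implemented because it matches "counting back
from the eighth recovery step" literally, and it is isolated in
`count_recovery_steps` should anyone need the alternative.

## Statistics

* Mixed two-way repeated-measures ANOVA: classical split-plot decomposition
  (between: group vs subjects-within-groups; within: step and group×step vs
  subject×step), exact sums-of-squares partition on balanced-within data,
  unequal group sizes supported with frequency-weighted marginal means.
  Greenhouse–Geisser correction is available but off by default, mirroring
  the integer-df reporting convention of the field.
* Mann-Whitney U reports U = min(U₁, U₂).  Recovery-step counts are small
  tied integers, so for samples of at most 8 per group the null is the
  full permutation distribution (all group labelings enumerated — valid
  under ties); larger samples use the tie-corrected normal approximation.
* Wilcoxon signed-rank: exact null for n ≤ 25 without ties, own sign-flip
  enumeration for tied data up to n = 14, tie-corrected normal beyond.
  Zero differences are dropped; an all-zero sample is flagged degenerate.
* Friedman: tie-corrected chi-square computed from within-block midranks;
  the closed form reduces to the sign test for two conditions.  Incomplete
  blocks raise — the intended fallback (as when a participant misses one
  perturbation) is pairwise Wilcoxon tests, which `PerturbationStudy`
  applies automatically.
* Dunnett many-to-one (each step vs Base, within subject): paired t
  statistics adjusted by seeded Monte-Carlo quantiles (10⁵ draws) of the
  maximum of a multivariate t with correlation estimated from the paired
  differences.  Adjusted p-values are clipped from below by the unadjusted
  ones.  Monte-Carlo was chosen over tabulated quantiles to support any
  number of comparisons and df.
* Sidak: `p_adj = 1 − (1 − p)^k`.
* Sample size for the between-group effect in a repeated-measures design
  uses noncentral-F power with the efficiency multiplier
  `m/(1 + (m−1)ρ)`; the assumed repeated-measures correlation ρ is an
  explicit argument because published power analyses of this design rarely
  report it, making their N impossible to verify without assumptions.
  (The power analysis convention `f = 0.5 ⇔ d = 1` for the two-group
  contrast is provided as `cohens_f_to_d`.)

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
musculoskeletal mechanics:

* **Step process.**  Step times, lengths and widths are lognormal with
  configurable means and CVs.  At a trial speed `v`, step time scales as
  `(v_ref/v)^0.5` from the reference cadence and step length is `v·T` —
  on a treadmill the mean step length must equal the belt travel per step.
  A weak per-step mean reversion (15% of the midline offset) keeps foot
  placements anchored without biasing realized means.  Double support is a
  configurable fraction of stride (default 0.14 per step, i.e. 28% of the
  stride cycle in double support).
* **Foot trajectories.**  Stance advects the hallux backward at the belt
  speed with a 40 ms C2 landing blend plus a catch-up phase that repays the
  blend's displacement deficit, so realized step lengths equal configured
  ones exactly in the noiseless limit.  Swing is a quintic with matched
  boundary velocities.  Trajectory segments are C2 at the events, so the
  12 Hz zero-phase filter reproduces positions at touchdowns to well under
  a millimetre.
* **Inverse-designed CoM.**  A smooth (pchip) XCoM target path is drawn
  through the constraints `c(td) = x_hallux − MoS_truth` and the CoM
  position integrates `x' = ω₀(c − x) − v_belt` (exact exponential-Euler
  recursion at 1 kHz).  The downstream identity `XCoM = x + (x' + v)/ω₀`
  then returns `c` exactly, giving the pipeline a per-step oracle.  The
  stance-side belt speed entering the ODE blends to the landing side's
  value over the last ~100 ms of swing, so it is continuous and agrees
  with the per-event lookup downstream.
* **MoS truth.**  Baseline per-step MoS follows a configurable monotone
  quadratic in speed (defaults cross 0.05 m near 1.35 m/s, in the range
  reported for older adults) plus Gaussian step noise (default 8 mm).
  Perturbation k displaces Post-step MoS by
  `initial_deviation·(1−adaptation)^(k−1)`, holding for `delay_steps` and
  then decaying geometrically (`recovery_rate` per step) with
  `response_sd` of superimposed noise.  Defaults (−0.15 m, rate 0.8,
  adaptation 0.25, sd 0.02 m) produce first-perturbation recovery counts
  around six steps, the scale reported for this protocol.  Preset profiles:
  `non_faller()` (adapting) and `faller()` (delay 1 step, sd 0.03,
  adaptation 0.05).
* **Forces and noise.**  Vertical GRF is a body-weight-scaled smoothed
  trapezoid per stance (40 ms half-cosine loading), crossing the 50 N
  threshold ~7 ms after true touchdown.  Marker noise is additive Gaussian
  (default 1 mm).  Real marker noise spectra and belt-controller lag are
  not characterized in the source protocols; both are assumptions exposed
  in configuration.
* **Protocol schedule.**  Ten perturbations (right, eight left, right) at
  unannounced 30–90 s intervals after a lead-in; onsets snap to the first
  qualifying swing crossing at or after the nominal time (nominal gaps are
  drawn from 31.5–88.5 s so realized gaps stay within 30–90 s).

What the generator does **not** emulate: frontal-plane balance, kinematic
responses of the trunk or arms, harness interaction, cross-belt stepping,
forefoot/heel strike differences, non-stationary fatigue or drift.
Passing tests therefore demonstrate that the pipeline recovers the
quantities it defines from data with the assumed structure — not that the
marker weighting or event thresholds are optimal for any particular
laboratory's raw data.

## Cohort simulators and problem sizes

Statistical calibration uses step-level simulators
(`simulate_mos_table`, `simulate_recovery_counts`) that draw directly from
the same response law the marker-level generator embeds, with a
between-participant baseline SD of 0.02 m.  Calibration of a test's type-I
error needs hundreds of cohorts, and the step-level law is the exact
marginal of the full generator for these quantities, so nothing is lost by
skipping marker synthesis there.  The test suite and acceptance script use
40 s unperturbed trials (about 80 steps), 8 speeds per participant, and
full marker-level perturbation sessions of about 6 minutes with shortened
(31–40 s) gaps; calibration suites use 100–200 replicate cohorts of
8 + 12 participants, matching the study design's group sizes.

## File formats

Trials are exchanged as plain CSV (markers at 100 Hz; forces and belt
speeds at 1000 Hz) with an optional JSON ground-truth sidecar; belt speeds
live on the force grid because perturbation ramps contain kinks that a
100 Hz grid would misplace by up to 5 mm of MoS.  A C3D reader is not
included; the CSV dialect is the interchange format.

## Known limitations

* The pendulum length and CoM weights are stand-ins validated against the
  generator, not against a full-body model.
* The exact-with-ties Wilcoxon branch enumerates 2^n sign patterns and is
  limited to n ≤ 14; between 15 and 25 with ties it falls back to the
  tie-corrected normal approximation.
* The mixed ANOVA handles unbalanced groups but requires complete
  within-participant data (no imputation), mirroring the protocol's switch
  to nonparametric pairwise tests for incomplete cases.
* `simulate_mos_table`'s Base level is the mean of ten baseline steps and
  so has one-tenth the step variance — a mild, deliberate sphericity
  violation inherited from the labeling definition itself.
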