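# Methods

## The paradigm and its encoding

The package analyzes a dual motor–cognitive task: reach-and-touch
movements toward virtual fruits under three visualization conditions
(IVR head-mounted display, optical see-through AR, 2D screen), with a
parallel out-loud counting task and post-hoc questionnaires. Two protocol
variants are encoded as data: the elderly-cohort variant (`exp1`, 102
fruits in blocks of 6, 12, 12, 12, 18, 18, 18 and 6; first and last
blocks pear-only, middle blocks containing all three fruit categories)
and the patient variant (`exp2`, 48 fruits in blocks of 6, 6, 6, 12, 12
and 6; blocks 2 and 4 restricted to pears and oranges, a 5 cm instead of
4 cm home sphere, and the workspace centered in front of the participant,
31 cm down and 40 cm forward of the eyes). Collider geometry is taken as
given: spheres of 10 cm (orange) and 7.52 cm (apple), and for the pear a
5.78 cm sphere topped by a vertical capsule 7.31 cm high and 2.38 cm in
diameter; the cursor sphere is 4 cm.

Axis convention: right-handed workspace frame with x = horizontal
(screen right), y = vertical (up), z = depth (away from the
participant). Lengths are meters, times seconds, everywhere except file
I/O where units are spelled out in column names.

### Target locations

The exact coordinates of the 22 target locations are not published, only
their depth-usage taxonomy: 8 locations without any depth component (2
horizontal-only, 2 vertical-only, 4 horizontal+vertical), 2 depth-only
(one nearer, one farther than center), and 12 combining depth with other
axes (8 three-axis, 4 depth+horizontal). The generator therefore places
targets at grid-aligned fractions (±1/3, ±2/3 of the half-extent) of the
workspace on each active axis, drawing the fraction per axis from a
seeded RNG. This preserves the class taxonomy and workspace bounds
without inventing authoritative coordinates. Unused axes are exact
zeros, so any depth-classification tolerance below the grid step works;
the default is 1 mm. The location set is canonical per seed and shared
across participants and conditions (whether the real experiment
re-randomized per participant is not documented; a fixed set is the
conservative choice for a crossed design).

## Synthetic data generator

The generator exists so every downstream stage is testable without human
recordings. It emulates the statistical structure the analysis assumes,
not the biomechanics of an arm.

* **Ground-truth reach**: minimum-jerk point-to-point movement,
  `p(τ) = p0 + (p1−p0)(10τ³−15τ⁴+6τ⁵)` — straight path, single speed
  peak of 1.875·D/T. The reach ends in contact with the fruit's collider
  (0.9 of the contact distance inside the surface, or half the
  target distance for targets closer than the collider radius).
* **Condition effects** (per-condition `ConditionEffectModel`):
  a duration multiplier on the baseline tempo; a half-sine lateral
  curvature bump (peak amplitude in meters, perpendicular direction
  seeded); a Poisson-distributed number of corrective submovements; an
  onset latency drawn from a non-negative truncated normal during which
  the hand holds the home position; and additive isotropic Gaussian
  position noise (default sd 1 mm, a typical tracker noise scale).
* **Submovements**: in generated trials, corrective submovements are
  sequential ~0.3 s minimum-jerk hops of ~2 cm closing a deliberate
  undershoot of the main reach. Corrections of this duration survive the
  10 Hz analysis filter and produce countable speed peaks; superimposing
  brief pulses on top of a 0.2–0.5 s reach would be both unphysiological
  and invisible after filtering. The superposition primitive
  (`add_submovements`) is still provided and obeys the 1+k-peaks rule
  for well-separated pulses on long reaches.
* **Timing**: timestamps are a uniform 2 ms grid plus 0.1 ms Gaussian
  jitter ("approximately 500 Hz"), forcing the analysis to resample.
* **Subjects**: a multiplicative lognormal tempo effect (sd 0.10) on a
  baseline of 3.0 s/m — an elderly-like reach tempo giving peak speeds
  around 0.6 m/s, comfortably above the 0.2 m/s onset threshold.
* **Default effect magnitudes** reproduce the ordering
  Screen > AR > IVR for duration, curvature, submovement rate and onset
  latency (duration scales 1.35 / 1.10 / 1.00; submovement rates
  2.5 / 1.0 / 0.5; onset means 0.60 / 0.42 / 0.35 s). The magnitudes are
  simulation parameters chosen once for plausibility, not empirical
  claims; a null configuration with identical conditions exists for
  calibration. A depth-usage duration multiplier (0.90 / 1.15 / 1.00 for
  no/only/combined depth) injects the depth effect direction.
* **Counting**: responses follow the participant's internal counter;
  with the configured error probability a response is off by one, and
  the participant keeps counting from the erroneous value (configurable
  probability of recovering to the truth instead).
* **Questionnaires**: integer Likert draws (SUS 10 items, IMI subscales
  of 7/5/5/5 items) and 0–100 sliders (RTLX, one per subscale) around
  instrument-typical means with a per-subject bias; optional
  per-condition location shifts, clipped to the instrument range with a
  warning when the shift pushes items out of range.

What the generator does **not** emulate: arm dynamics and posture,
assistive-device interaction, VR rendering latency, endpoint error
(every simulated reach ends in contact), non-Gaussian tracker glitches,
and the surplus segments present in real recordings (restarted reaches).
Passing tests therefore demonstrate correctness of the measurement and
statistics chain under the stated generative model, not validity on real
data.

## Kinematic processing

* **Segmentation**: one segment per fruit, from the fruit-appearance
  event to the collision event; return-to-home samples are excluded; an
  appearance without a subsequent collision drops that trial with a
  logged warning.
* **Velocity estimation** (the source experiment does not document its
  differentiation): linear resampling onto a uniform 500 Hz grid,
  zero-phase 4th-order Butterworth low-pass at 10 Hz on the *positions*,
  central differences, then the speed magnitude. Filtering must precede
  rectification: the magnitude of zero-mean 3D noise has a large positive
  mean (~0.5 m/s at 1 mm noise and 500 Hz) that no filter applied after
  the fact can remove. The filter pad length is ~3 filter time constants
  (3·fs/cutoff samples) so edge transients decay inside the padding, not
  inside the segment.
* **Metrics**: duration and chord use the segment's first/last samples;
  path length uses the filtered positions by default (config option
  `path_positions="raw"`), consistent with the speed profile. For a
  noise-free straight reach filtering is exactly path-neutral
  (collinearity and monotonicity are preserved by a linear zero-phase
  filter), so straightness stays 1 to machine precision.
* **Velocity-peak counting**: local maxima with prominence
  ≥ max(0.02 m/s, 5% of peak speed) and separation ≥ 50 ms — suppresses
  residual noise maxima while keeping genuine corrective submovements;
  both thresholds are configurable.
* **Onset**: first sample with speed ≥ 0.2 m/s, reported relative to
  fruit appearance; absent (and excluded listwise from the onset model
  only) when the threshold is never reached.
* **Degenerate segments**: chord below 1 mm makes the chord-normalized
  metrics undefined; they are reported absent with a log entry.
* **Extreme outliers**: per metric, values strictly outside
  [Q1 − 3·IQR, Q3 + 3·IQR] are removed in a single pass (no re-fencing);
  quartiles use linear interpolation between order statistics, the
  default convention of the scientific Python stack, and the convention
  is configurable only in the sense that fences depend on it — it is
  documented rather than swappable. Grouping defaults to pooled per
  participant across conditions (`per_condition` available): the removal
  rule is stated per participant, while removal counts are reported per
  condition, so both readings are supported.

## Statistics

Cell values entering the repeated-measures models are per-participant
cell means of segment-level metrics (medians available via the
aggregation config); the aggregation level is not documented in the
source, and means are the conventional choice.

* **Two-way RM-ANOVA** (3 visualization × 3 depth-usage, fully within):
  classical sums-of-squares decomposition, each effect tested against
  its own effect-by-subject interaction. Sphericity is assessed per
  effect with Mauchly's test on the effect's orthonormal contrast space
  (main effects collapse the other factor first; the interaction uses
  the Kronecker product of the factor contrasts — the afex/SPSS
  convention). The Greenhouse–Geisser ε (Box's formula, clipped to
  [1/(k−1), 1]) and the GG-corrected p are always reported; the
  "selected" p uses the correction only when Mauchly rejects at α.
  Partial η² = SS_effect/(SS_effect+SS_error). The harness is
  implemented directly rather than delegated because the established
  Python implementation warns that its own two-way ε may be inaccurate
  with two 3-level factors; it serves instead as an independent
  cross-check in the tests, alongside a brute-force SS oracle.
* **One-way RM-MANOVA** (questionnaire subscales as joint DVs): Wilks'
  λ = |E|/|E+H| on the stacked within-subject contrast scores; with the
  one-sample structure there is a single nonzero root, the F transform
  F = ((n−m)/m)(1−λ)/λ with df (m, n−m) is exact, and the reported
  effect size is 1−λ (the partial η² convention 1−λ^{1/s} with s = 1,
  labeled explicitly in the output since the convention used by
  commercial software cannot be verified from printed values). The test
  requires m = n_DVs·(k−1) < n; with small samples (e.g. 5 patients and
  4 IMI subscales) it is reported as not estimable rather than forced.
* **Friedman test** with mid-rank ties and the standard tie correction;
  Kendall's W = χ²/(n(k−1)); a fully tied table yields χ² = 0 by
  convention.
* **Post-hoc**: paired t-tests, Bonferroni adjustment
  p_adj = min(1, m·p), Cohen's d defaulting to d_z = mean(diff)/sd(diff)
  (d_av available; the variant used by the source is unnamed).
  Zero-variance differences are flagged degenerate with |t| = ∞ when the
  means differ.

### Calibration studies

Monte-Carlo checks of the harness run on a cell-level generator that
draws per-participant 3×3 cell means directly from the same effect model
as the trajectory simulator (baseline × condition scale × depth scale ×
subject effect, plus subject-by-condition noise sd 0.10 and residual
noise sd 0.15 s/m). Problem sizes: 1000 null replicates for type-I error
(measured ≈5% at α = 0.05 for n = 17), 200 replicates each for power of
the visualization effect and recovery of the injected
Screen > AR > IVR ordering (both ≈100% at the default effect sizes).
Running these on full trajectory datasets would add nothing to the
questions they answer — they test the statistics, not the kinematics —
so the trajectory layer is exercised separately by the pipeline tests
(e.g. the 5-patient design segmenting into exactly 720 reaches).

## Pipeline and reproducibility

All stages are deterministic given the config seed; child seeds for
simulation, counting and questionnaires derive from it via
`SeedSequence`. Outputs are plain CSV/TSV/JSON with fixed float
formatting, so a rerun with the same config is byte-identical; the
manifest records per-stage record counts (segments in = kept + removed +
metric-absent, reconcilable per metric), per-condition outlier tallies,
and SHA-256 hashes of every output file.

## Known limitations

* The generator's effect magnitudes and noise scales are plausibility
  choices; parameter recovery results quantify the harness under this
  model only.
* Smoothness is measured only as the velocity-peak count; jerk-based or
  spectral measures are out of scope, as is orientation/quaternion
  analysis.
* The RM-ANOVA is used as-is on possibly non-normal metrics (as in the
  source analysis); no non-parametric alternative for the two-way
  within design is provided.
* The counting scorer's acceptance set {true count, last said + 1} is
  the most permissive reading consistent with the documented example;
  stricter readings (carry-forward only) would score recoveries to the
  true count as errors.
* Real-data ingestion is limited to the pipeline's own long CSV format;
  an adapter for the public deposit of the original recordings would be
  a separate, additive component.
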