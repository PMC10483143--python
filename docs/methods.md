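# Methods

## Coordinate and quadrant conventions

Arena coordinates are in cm with the origin at the lower-left corner and y
increasing upward; trajectory CSVs record this convention implicitly via
their column names, and pixel input is converted by a single `px_per_cm`
scale. Physical quadrants are labeled A (lower-left), B (lower-right),
C (upper-left), D (upper-right). Quadrant membership uses half-open
midline intervals — `[0, W/2)` is left, `[W/2, W]` right, same for y — so
assignment is total and deterministic including exact midline points.

Quadrant *roles* (Q1 silence, Q2–Q4 tones, ordered by ascending frequency)
are decoupled from physical corners. All analysis is performed in role
space; the role→corner map is what gets randomized across animal pairs.
Counterbalancing places the silent role in each corner exactly once per
block of four pairs (seeded permutations; a remainder block is drawn
without replacement), and by default also permutes the three tone roles
among the remaining corners. Permuting all four roles (not only silence)
is the stronger balancing choice and subsumes the weaker reading of the
randomization; a config flag restores silence-only permutation.

## Closed-loop engine

The controller replays a position stream into the tone-command stream the
speaker would have produced. During the habituation phase the output is
silence regardless of position. Afterwards the active tone is the tone of
the occupied quadrant's role, with Q1 mapping to silence. Two modeling
choices the physical rig leaves open:

- **Debounce.** A quadrant change takes effect only after 2 consecutive
  frames (100 ms at 20 fps) in the new quadrant. Without this, centroid
  noise at a virtual boundary produces artifactual tone flicker. The first
  observed position is adopted immediately.
- **Dropouts and latency.** On tracking loss the engine holds the last
  confirmed quadrant (a real-time system cannot act on absent data);
  actuation latency is modeled as zero and tone switching as instantaneous.

The event log records only transitions, with strictly increasing
timestamps, and replay is a pure function of (trajectory, schedule,
assignment).

## Tracking

The tracker is a deliberate minimal stand-in for an external real-time
tracker: threshold the frame, take the intensity-weighted center of mass of
above-threshold pixels, convert to cm. The synthetic convention renders
the animal bright on a dark background (the assay runs in darkness under IR
illumination; polarity is a rendering choice here). A frame with no pixel
above threshold is a dropout — a value, not an error. Gaps of at most 10
frames (0.5 s) are forward-filled with the last valid position so the
engine can ride across them, but remain flagged invalid and are excluded
from every analysis denominator. On noise-free rendered frames the
round-trip error is below 0.5 px; tests verify the error grows
monotonically with additive noise.

## Metrics

- Occupancy over a window `[t0, t1)` counts valid frames per role times the
  frame period; fractions are over valid frames only, so they always sum
  to 1. An empty window is an error, not a zero.
- The preference index subtracts phase-time *fractions* (×100), not raw
  seconds: the phases differ in duration (5 vs 30 min), so only fractions
  are comparable. Components sum to 0 by construction.
- The binned time course uses one habituation bin plus 5-min exposure bins;
  a non-dividing final bin is truncated and flagged.
- AUC is the trapezoidal integral of a role's per-bin fraction against bin
  midpoints in minutes from exposure onset, exposure bins only (six 5-min
  bins span 25 midpoint-minutes, so constant occupancy f gives 25·f).
  Whether to integrate fractions or raw minutes, and whether to include
  habituation, are conventions the assay's figures leave open; both are
  switchable, with the stated default.
- Distance sums Euclidean steps between consecutive valid frames, each step
  attributed to the role of its starting frame; steps implying speed above
  100 cm/s are discarded as tracking artifacts.
- Heat maps are 2-D histograms of valid positions weighted by the frame
  period; total mass equals valid time.

## Statistics

`students_t` is the pooled-variance two-tailed test (df = n₁+n₂−2; a paired
variant exists — the silent-vs-tone-mean comparison is run unpaired by
default to match the df structure this assay conventionally reports, even
though the data are within-animal). `one_way_anova` is the classical
between/within decomposition with Tukey HSD post-hocs. If every
observation is identical the test returns F = 0, p = 1 with a degeneracy
note instead of raising.

The two-way repeated-measures ANOVA partitions SS into factor A, factor B,
A×B, subject, and the three matching error strata on a complete balanced
within-subject design; missing cells raise an error naming the subject and
cell. Sphericity is uncorrected by default (matching the commercial
defaults of the era this assay comes from); `gg_correction=True` applies
per-effect Greenhouse–Geisser epsilon computed from orthonormal-contrast
projections of the subject×cell covariance. Tukey comparisons of marginal
means use the factor's own error stratum.

Quadrant fractions are compositional (sum to 1, not independent); the
tests are run as conventionally published for this assay and every result
carries a metadata note recording the violation rather than "correcting"
it. CI level is 95 % throughout (the overwhelming convention where the
assay's reports leave it unstated).

## Simulators

Two generators, by design:

- **Agent model** (integration tests, demo cohorts): a discrete-time
  correlated random walk at 20 fps. Heading receives wrapped-normal noise
  (SD 0.25 rad/frame, i.e. ~1 s heading persistence — straighter runs, as
  actively exploring mice make); step length is gamma-distributed with mean
  8 cm/frame·fps⁻¹ (8 cm/s average speed, within the range open-field mice
  sustain) and shape 2; walls reflect. The closed-loop engine runs
  internally, so the tone state is known: while a tone is audible and the
  session time exceeds the first tone exposure plus `onset_latency_s`, the
  heading is reset toward the silent quadrant's centroid (plus 0.3 rad
  noise) with probability `avoidance_strength`/fps per frame. With zero
  avoidance the model is symmetric, so expected occupancy is exactly 25 %
  per quadrant; agents start at the arena center, as animals are placed.
- **Dwell model** (estimator-recovery tests): segments draw a role i.i.d.
  from a requested stationary vector and hold it for an exponential dwell
  (mean 20 s), making the expected time fraction per role *exactly* the
  requested vector at any horizon; within a segment the position follows a
  small bounded random walk inside the role's quadrant, kept 0.5 cm off the
  virtual boundaries. A segment-level bookkeeping path (`dwell_fractions`)
  returns exact realized fractions without per-frame rendering; it backs
  the 1,000-cohort type-I calibration, and is itself checked against the
  per-frame pipeline.

Packaged agent profiles (`data/profiles.yaml`): `wt` has no sound
response; `ko` reorients toward silence (strength 0.6/s) starting 15 min
after first tone exposure, which lifts whole-exposure silent occupancy
into the mid-40s percent range while leaving the first exposure bins at
baseline — the avoidance-with-delayed-onset phenotype class. These are
tuning constants, deliberately in config rather than code.

Neither generator claims biological realism: no thigmotaxis, rearing,
grooming, pauses, or between-animal dispersion structure. Passing tests
therefore demonstrate correctness of the pipeline's accounting and the
statistical machinery under known ground truth, not fidelity to real mouse
behavior.

Cohorts pair one WT and one KO per assignment (shared within the pair,
counterbalanced across pairs); per-session seeds fan out from the master
seed by counter, so growing a cohort never reshuffles earlier sessions.

## Problem sizes and numerical choices

The headline checks use 100 agents × 5 min for the null baseline and 50
dwell sessions × 35 min per recovery condition — enough for Monte-Carlo
SEs of ~0.9–1.1 percentage points against ±2-point bands, while the whole
reproduction script completes in seconds. The type-I calibration uses
1,000 cohorts of 4×6 sessions at the segment level. Equality tests
against brute-force sums-of-squares oracles use 1e-9–1e-10 absolute
tolerances; occupancy/preference conservation identities 1e-9;
trajectory round-trips 1e-6 (the CSV precision). Degenerate inputs (zero
variance, empty windows, missing cells, non-monotone time) raise typed
errors rather than propagating NaN, except the all-identical ANOVA input
noted above.

## Known limitations

- The engine's debounce length and dropout policy are modeling choices the
  physical rig does not document; both are constants that can be changed in
  one place.
- The unpaired silent-vs-tone-mean t-test ignores the within-animal
  pairing (kept for df compatibility; the paired variant is one flag away).
- ANOVA on compositional fractions inflates dependence between levels; the
  RM machinery reports it but does not remodel it.
- The tracker does not emulate any real tracker's smoothing or failure
  modes.
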