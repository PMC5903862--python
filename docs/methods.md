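# Methods

`nmregen` analyzes whole-organ regeneration of zebrafish lateral-line
neuromasts from long-term single-cell tracking data, and ships an
agent-based simulator of the same process so that every stage of the
pipeline can be exercised and validated without access to tracking data.
This note records the models, conventions, parameter choices and known
limitations.

## Data model

A *track table* holds one row per cell per frame: experiment id, lineage
id, heap node index, time in hours post injury (hpi), position in µm and a
cell-class label (S sustentacular, M mantle, H hair, U unassigned).
Lineages use the heap encoding: the founder is node 1 and the daughters of
node *n* are 2n and 2n+1, so generation(n) = ⌊log₂ n⌋.  Heap indices are
scoped per lineage because a global numbering collides across founders.
Hair cells are postmitotic, so the only class changes a valid table may
contain are S→M, S→H and U→{S,M,H}.

A division is recorded at the dividing cell's **last** frame; daughters
appear one frame later.  Cell-cycle length is the time from a cell's birth
to its own division, and for founder cells from the recording start
(4 hpi).  Founder first-division times are reported in hpi.  A sanity gate
(default 15 µm, configurable) rejects daughters appearing far from their
parent's last position.

Clones are typed by the set of classes among their member cells at the
last recorded frame: S, SM, SH, SHM for sustentacular founders, M for
mantle founders; any other composition (e.g. a pure-hair clone) maps to
OTHER and is flagged rather than dropped, so anomalies in real data stay
visible.  Divisions are categorized by the two daughters' fates, each
assessed at the daughter's own next division or at the end of the
recording: SS, HH, MM (symmetric) and SM (asymmetric).

## Organ frame and spatial statistics

The organ frame puts the origin at the centroid of the first frame's
cells (recordings are registration-centered upstream, so the origin is
fixed for the whole movie; a per-frame-centroid mode exists behind a
config switch), with +x posterior and +y dorsal applied from the manifest's
axis convention.  Quadrants are the four 90° sectors whose bisectors are
the compass axes, half-open at the 45° diagonals.  All geometry is 2-D:
the neuromast is a roughly planar cuboidal epithelium, and the feature
catalog lists only x and y coordinates; z is carried through files but
unused.

Progeny laterality assigns each founder a side by the sign of its
first-frame coordinate on the chosen axis and reports the fraction of its
clone (cells alive at the assessment time, 60 hpi by default) found on the
same side.  Cells exactly on the midline are excluded from the fraction
but counted.

## Kinetics

Division waves are read off a Gaussian-kernel smoothed density of
division times (bandwidth 1 h by default; the wave tests use 1.5 h, which
matches the within-experiment coordination of the simulator); peaks
require a prominence of at least 10% of the global maximum.

The relation of cycle length to regeneration time (or to organ size) is
summarized by a continuous two-segment ("broken-stick") least-squares
regression.  Continuity at the change point is enforced — the standard
segmented-regression convention, and the natural reading of a cycle length
that first drifts slowly and then rises.  The change point is found by
exhaustive search over the distinct interior x values and the midpoints
between neighbors, with at least 5 points per segment; each candidate fit
is linear and solved by least squares, so the estimator is deterministic,
exactly reproducible, and never worse than the single-line fit (nested
models).  A fit whose error equals the single line's is flagged
degenerate.  For cycle-versus-size fits each completed cycle is paired
with the total cell count at the cycle's start.

## The 32 predictors

Features describe one cell at one timepoint: time; absolute, normalized
(by the currently furthest cell) and angular position; distances to the
nearest and average H, M and S cells (excluding the subject); counts of
each class in total and within 10/20/30 µm (whole-organ counts include the
subject, radius counts are neighbor counts); generation, founder class,
founder count and total cell count; and movement relative to the cell's
last division (its birth division, or the recording start for founders):
elapsed time, distance moved, the change of radial distance (positive when
toward the center), and the angle at the organ center between current and
last-division locations (the catalog names three points without fixing
the vertex; vertex-at-center is the default, vertex-at-last-division is a
config switch).  When a class is absent (no hair cells early in
regeneration) its distance features are set to a finite 100 µm sentinel
and the row is flagged — tree learners need finite inputs.  Extraction is
verified against a naive double-loop oracle to 1e-9 µm.

## Fate prediction

A bagged random forest (200 trees, unlimited depth, √32 features per
split, fixed seed) discriminates binary fate choices at two levels: clone
composition of a sustentacular founder (SH vs SM, S vs SH, S vs SM) and
division category (HH vs SM/MM, SS vs HH, SS vs SM/MM; the two
mantle-producing categories are merged).  Row policies: clone tasks use
the founder's coordinates from the recording start to its first division;
division tasks use the dividing cell's coordinates over a window of w
frames ending at the division (default w = 1).

Validation is round-robin leave-one-experiment-out: train on N−1
experiments, test on the held-out one, for each experiment in turn; train
and test experiments are disjoint by construction and asserted at run
time.  Row predictions are aggregated per entity (clone or division) by
majority vote; exact ties count as incorrect.  Scores use the Matthews
correlation coefficient, MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
with the standard convention MCC = 0 when a denominator factor vanishes.
Score spread is estimated by resampling 15 experiment-level test sets with
replacement 15 times and recomputing the pooled MCC (row-level resampling
is available behind the `sample_size` argument).  Feature importance is
permutation importance on held-out rows, averaged over folds.

## The synthetic regeneration generator

The generator emulates the tracked study conditions: 15 independent
recordings, each starting 4 hpi from 2–3 mantle founders seated at the
organ rim and 2–7 sustentacular founders inside (uniform in the ranges,
4–10 cells total), one frame per 0.25 h, durations uniform in 65–100 h.

**Timing.**  Sustentacular founders divide at times marginally distributed
as Normal(19, 6) hpi, decomposed into a per-experiment wave anchor
(sd ≈ 4.5 h) plus within-experiment jitter (sd 4 h) — founder divisions
are coordinated within an organ, which is what makes division waves
emerge.  Mantle founders divide with probability 16/30 at Normal(27, 5)
hpi; mantle lineages divide only MM and at most twice.  Subsequent cycles
are Normal(11, 3) h (truncated ≥ 4 h), likewise split into a
per-experiment generation spacing and per-cell jitter.  After the time
change point (47 hpi) cycles lengthen by 1 h per hour of birth delay plus
extra noise; a size-based rule (1.5 h/cell beyond 24 cells) and a combined
mode are selectable, with the time rule the default because applying both
additively freezes the simulation by ~50 hpi.

**Growth control.**  Sustentacular daughters become quiescent with a
probability that ramps from 0 at 11 cells to 0.95 at 25 cells, multiplied
by a centrality factor (zero at the center, full beyond 60% of the organ
radius): central progenitors keep cycling longest, the rim settles first.
After 60 hpi, scheduled divisions are retained with probability
0.25 + 0.75·sin²θ, restoring the homeostatic dorsoventral proliferative
territories.  These two mechanisms are the generator's free design: the
stated timing and fate parameters alone produce unbounded exponential
growth, while the tracked organs settle near ~45 cells.  Their constants
were calibrated once against the division-per-founder count, the cell
count at 72 hpi and the late polar division bias, before the acceptance
checks were run.

**Fates.**  Division categories follow base probabilities
(SS, HH, MM, SM) = (0.78, 0.16, 0.03, 0.03) with spatial structure imposed
by a propose/accept quota: a per-experiment quota proposes the category
whose realized count lags its target, and the proposal is accepted with a
spatial eligibility — SS fits everywhere (mildly damped in the deep center
once hair production starts), HH only inside the central macula
(eligibility falling to zero at 85% of the normalized radius, zero before
hair-cell onset at 48 hpi, dorsoventrally weighted after 60 hpi), MM/SM
only in the perimetral band beyond 55%, damped near existing mantle
cells.  Rejected proposals keep their deficit and wait for a division
where they fit.  This separates *how often* each category occurs (the
quota keeps marginals at their targets regardless of when divisions
happen) from *where* it occurs (the eligibilities place HH centrally and
MM/SM peripherally), reproducing both the marginal fractions and the
ring-like division map.  HH daughters are hair cells and terminal; MM/SM
mantle daughters do not cycle further.

**Geometry.**  Daughters appear one frame after the division at the
parent's position ± a mirrored Normal(0, 3 µm) per-axis displacement
(clipped to 10 µm so the lineage sanity gate always holds); every cell
then random-walks with Normal(0, 0.4 µm) per axis per frame.  The organ
radius grows as R(t) = R₀·√(N/N₀) (constant areal density, R₀ = 20 µm),
smoothed to at most 2% expansion per frame; positions scale with the
radius (uniform areal tissue growth) and are clamped inside it.  Clones
therefore stay cohesive and mostly ipsilateral to their founder.

**Null variant.**  `null_variant` toggles off all spatial and temporal
fate structure: categories become i.i.d. draws from the base
probabilities, and the position-dependent parts of division pressure are
replaced by position-independent averages.  Marginals are unchanged; no
feature carries fate information, so classifier scores calibrate to zero.

**Ground truth** (clone types, division categories, class timelines) is
emitted alongside each table and is exactly recomputable from the table
by the pipeline — asserted in the test suite.

### What the generator does not emulate

No cell death, no interneuromast-cell immigration, no mechanistic
signaling (Notch/Fgf/Wnt), no 3-D mechanics or planar polarity, no
tracking errors or gaps.  Division counts per founder (~6) run somewhat
above the tracked estimate (~4), the price of supplying enough
post-onset divisions to absorb the hair-cell quota; consequently clones
are somewhat larger and cohort cell counts at 72 hpi (typically 35–65)
sit at or above the real trajectory.  Passing tests therefore demonstrate
that the pipeline recovers planted structure of realistic shape and
magnitude from track tables alone — not that the generator is a
biophysical model of the organ.

## Problem sizes and estimator precision

Statistical checks run at sizes where their expected sampling error is
well inside the asserted tolerance: fate marginals pool ≥1000
sustentacular divisions (three cohorts); founder-timing recovery pools 150
experiments because the per-experiment wave anchor dominates the variance
of the mean (SE ≈ 0.45 h); the first division wave is measured as the
pooled density peak of generation-0 division times, the founders'
coordinated division being the first wave; null-model calibration of the
clone-level tasks averages over eight independent null cohorts because a
single cohort holds only ~20–50 labeled clones and an entity-level MCC on
so few entities has an irreducible sampling spread of ~0.2.

## Numerical conventions

Times snap to the 0.25 h acquisition grid; grid membership is checked to
1e-6.  Track files store floats at µm/h precision 1e-6 with deterministic
row and column order, so write∘read is byte-stable.  The polar angle is
undefined at the origin and raises; the feature extraction substitutes 0°
for a cell exactly at the center (flaggable case, never observed in
simulation).  `normalized_distance_to_center` is defined as 0 when every
cell sits at the origin.  Random-forest fold seeds derive from the config
seed plus the fold index; all simulator randomness flows from
`numpy.random.SeedSequence`, and derived seeds stay below 2³¹.
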