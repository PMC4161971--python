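# Methods

This note documents the models, conventions and numerical choices behind
`morphtrack`, in the order data flows through the package.

## Track geometry

**Track A.** Ten rigid segments (default 40 cm, the upper end of the
physical 35–40 cm range, so the linearized length is exactly 4 m), joined by
zero-length connectors on the midline. The joint discs of the physical
apparatus carry no arc length of their own, and assigning them none keeps
the linearized total at the stated 4 m. Segments 1–4 form the top arm, 5–6
the static base, 7–10 the bottom arm. Room coordinates are cm, origin at the
base arm's outer corner, y toward the top arm.

Each arm folds as a one-sided accordion: with extent e (the well's
horizontal reach) and θ = arccos(e / 160), segment directions alternate ±θ
about the arm axis, so odd vertices leave the axis by 40·sin θ while even
vertices and the food well stay on it. This satisfies the equal-angle
constraint (every joint angle equals 180° − 2θ = α) and leaves the well on
the arm axis, which the vertical-section indexing requires. The exact
contracted zigzag shape is not uniquely determined by the constraint; the
all-angles-equal fold is the symmetric choice.

**Vertical sections.** Twelve 9 cm sections per arm index pose similarity.
Twelve sections cover 108 cm, whereas the arm endpoints can physically
travel ~140 cm; the two printed numbers cannot both describe the sampled
sweep. We anchor the section grid at full extension and treat the 108 cm
grid as the operational sweep (extents in [52, 160] cm): the schedule
sampler draws poses on the grid, and `vertical_section_of` is defined there,
while `layout_planar` accepts the wider physical range. Sections use
half-open intervals with index 1 most contracted and 12 fully extended.

**Linearization.** x_L is arc length from well F1 along the midline
polyline, y_L the signed perpendicular offset (positive left of travel).
Because segments are rigid and joints carry no length, the x_L of a material
point is identical in every pose — the linear frame is exactly the track's
own frame. Planar→linear→planar round trips are exact to floating point;
the reverse assignment (projecting an off-midline point near a fold vertex)
can land on the adjacent leg, which is why session files persist both
coordinate sets.

**Track B.** Eleven 40 cm segments (440 cm path ≈ the stated 4.5 m) on a
U whose main-line *skeleton* is 9 segment slots (360 cm): arms of four
slots, a one-slot base. The three-segment protrusion is a rectangular
detour (out, across, back) occupying one skeleton slot — slot 3 on the top
arm or slot 7 on the bottom arm — so that inserting it stretches 40 cm of
skeleton into 120 cm of path. In the traversal numbering this places the
detour at sections 3–5 or 7–9, its center segment at 4 or 8, and the
straight section replacing it after the flip at 3 or 9, matching the
protocol's description. Both poses have the same path length: the flip is a
local deformation that preserves the track's connectivity.

## Synthetic sessions

**Schedule.** A session is `n_moves` configuration epochs (default 40, the
protocol's average; 10–80 supported). Both arm extents are re-drawn at
every move, executed during the reward pause. Extents are sampled by
shuffled decks of the 12 section labels (uniform within a section), which
guarantees the N_V ≥ 3 coverage contract whenever n_moves ≥ 36 — iid
uniform sampling would satisfy it with probability near zero at 40 moves —
while keeping the two arms' sequences independent (|r| < 0.2 over 200
moves). Schedules that cannot reach coverage are flagged, not rejected.

**Behaviour.** The animal alternates F1→F2→F1…, pausing ~8 s at each well;
forward speed is constant within a run, drawn per run around 11.8 cm/s so a
4 m run takes ~34 s. Lateral wobble is a box-smoothed OU process (s.d.
2 cm while running, 0.3 cm while paused) clipped to the 8 cm track width.
Sampling is 25 Hz. These plumbing values are conventions calibrated to the
printed run time and track width; the analysis nowhere depends on them
beyond the speed filter's 3 cm/s floor.

**Place cells.** One Gaussian field per cell:
rate = baseline + (peak − baseline) · g_c · exp(−Δ²/2σ²), with Δ the
distance to the field center *in the cell's anchored frame* and g_c an
optional per-pose rate-remapping gain. Anchorings:

* `planar` — Δ is room-frame Euclidean distance to a fixed point (sampled
  on the midline of a random reachable pose, so the track visits it often);
* `linear_fraction` — the center sits at a fixed fraction of the track's
  elastic skeleton and Δ is measured in skeleton coordinates. On Track A the
  skeleton is the (pose-invariant) arc length; on Track B the skeleton is
  the 360 cm main line, so a field caught by the protrusion stretches three-
  fold with it and shrinks back when the protrusion is removed — the
  topological (stretching) hypothesis. Defining the fraction on the whole
  440 cm path instead would be degenerate: both poses have equal total
  length, so fields would never move and the Distance comparison would
  trivially win;
* `segment_bound` — the center is a material point (segment, within-segment
  fraction) and follows that segment wherever it lies;
* `distance_from_well` — the center sits at a fixed arc distance from one
  well.

Defaults peak 15 Hz, baseline 0.1 Hz, σ = 10 cm. The baseline matters: it
scatters occasional spikes over the whole track, which is what makes
correlations between windows where a cell has no field *defined but near
zero* rather than undefined — the regime the protrusion battery's Flip and
Distance bars live in. Spikes are an inhomogeneous Poisson process realised
by thinning against the cell's maximum rate, with rates piecewise constant
at the sampling resolution; one deterministic sub-stream per cell.

## Rate maps

Speed is the central difference of 5-sample box-smoothed room positions
(odd-reflection padding keeps uniform motion uniform at the session edges);
samples and spikes below 3 cm/s are excluded everywhere. Occupancy assigns
each inter-sample interval to its first sample's bin. Maps use 3 × 3 cm
bins; per random offset (uniform within ± half a bin per axis, default 25
offsets, seeded) rate = count/occupancy is computed on the shifted grid and
averaged per bin over the offsets in which the bin was visited. Offsets are
shared across all maps that will be correlated in a run. Unvisited bins are
NaN, never zero, so empty space can never inflate a correlation. No other
smoothing is applied. Linear-frame grids span the track length × three
lateral bins (plus padding for the shifts); Track B comparisons use a
lateral-collapsed profile grid (3 cm × full width, shifted along the track
only), since those comparisons are defined on the linearized coordinate
alone.

The per-cell field-center estimate and the mobile/static split also use the
full-session profile map: a full-width x_L bin accumulates seconds of
occupancy where a 3 × 3 cm bin may hold one 40 ms visit, and a single stray
spike in such a bin would otherwise dominate the peak. With the profile
estimator ~98% of simulated elastic cells are recovered within 1.5 bins of
the true center; with 3 × 3 bins, 60–80%.

## Track A correlations

Poses are grouped per arm by vertical section (groups under 3 members are
dropped and logged). Per cell, occupancy and counts are pooled across a
group's epochs *before* normalization, restricted to the cell's region
(mobile span of its arm, or the base span for static cells) — pooling maps
rather than averaging them keeps the estimate a true occupancy-normalized
rate. Static cells' data do not depend on either arm's pose; they are
indexed by the top arm's sections (the choice is immaterial and exposed).

C_ij is the Pearson correlation of the two masked activity vectors; a bin
enters the mask if visited in both groups and carrying at least one spike
in either (the stricter spike-in-both variant is available as
`mask_rule="both"`; the inclusion clause is ambiguous in prose and the
choice is surfaced, not silent). Entries with fewer than `min_bins = 10`
masked bins or zero variance are undefined and excluded from every average,
never imputed. r_d is the mean over defined entries of the |i−j| = d
subdiagonal; ensemble curves average per-cell matrices element-wise first,
with SEM across cells (the across-entries alternative is not used). The
frame test is Welch's unequal-variance t-test on the pooled 1D vs 2D entry
sets at each d. Directions of travel are pooled by default (`direction`
selects one if wanted).

## Track B battery

Both sessions are mapped on the shared profile grid. The spec-level
inclusion rule (peak ≥ 2 Hz anywhere, either session) is implemented as
`include_active_cells`; the end-to-end driver then restricts the battery to
cells whose peak on session 1's protrusion span clears the same 2 Hz floor,
because all four comparisons correlate the firing *over that protrusion*
and cells that never fire there contribute identical sampling noise to all
four bars. Under every anchoring hypothesis the informative cells are
active there in session 1, so the restriction is hypothesis-neutral; the
unrestricted count is reported alongside (`n_active` vs `n_included`).

Windows use only bins lying entirely inside their span (an edge bin mixes
in- and out-of-window data), aligned by nearest bin center after the
coordinate map: identity for Distance (equal total lengths make
equal-well-distance equal-x_L), a 160 cm translation for Flip (materials
aligned in traversal order; the protocol fixes the center pairing 4↔8, the
outer order is a convention), and an affine map for Segment. Rescaled
compresses session 1's protrusion-span coordinates (samples and spikes)
affinely onto the replacing section and re-bins on the common grid — the
map moves coordinates only, so spike counts and occupancy are conserved
exactly. Statistics: pairwise two-sided Mann–Whitney u-tests, one-way ANOVA
and Tukey–Kramer post-hocs (scipy's `tukey_hsd`, which handles unequal n);
undefined per-cell values are excluded. An F statistic that underflows to a
tiny negative value for identical groups is reported as p = 1.

## What the synthetic data does and does not show

The generator reproduces the features the analysis relies on: the
alternation structure, pose changes during pauses, the sparse-pass regime
(≈3–4 passes per section group, matching the stated 3–7), single Gaussian
fields, and Poisson variability. It omits theta modulation and phase
precession, bursting and refractoriness, interneurons, overdispersion
beyond Poisson, global remapping, tracking noise, and cross-day
instability. Passing tests therefore show that the *analysis* separates the
coding hypotheses it was designed to separate under its own stated
assumptions — not that real CA1 data are this clean; on real recordings the
correlations would be lower throughout (as the protrusion experiment's
published values are relative to the accordion track's).

## Problem sizes and determinism

The shipped checks use five 50-cell, 40-move Track A sessions per anchoring
and Track B pairs of two 20-min sessions with 100 cells (20 replicates per
anchoring for the identification rate) — sizes at which every qualitative
contrast is far from its decision boundary while a full run stays in the
minutes range. All randomness flows from one master seed through named
SeedSequence sub-streams (schedule / trajectory / cells / per-cell spikes /
grid shifts), so identical inputs and seeds reproduce results byte for
byte.

## Known limitations

* Linearizing an off-midline point very close to a fold vertex can assign
  it to the adjacent leg (~2% of samples in tightly contracted poses);
  session files therefore carry both coordinate sets, and the projection
  path is a fallback for external tables.
* The bottom arm's printed small section offset is not modelled (its value
  is unpublished; default 0).
* `segment_correlation` compares only the protrusion's center segment, as
  specified; a three-segment variant would be a different statistic.
* The schedule moves both arms during one pause; with strict
  one-arm-per-pause alternation the N_V ≥ 3 coverage needed by the analysis
  is unreachable at 40 moves (20 poses per arm over 12 sections).
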