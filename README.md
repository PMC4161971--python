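# morphtrack

Dual-reference-frame place-field analysis on morphing linear tracks, with a
synthetic generator of place-cell recordings under competing coding
hypotheses.

Hippocampal place cells fire when an animal occupies a restricted region of
space — but *which* space? If the place map is a Cartesian chart of the room,
fields should stay put in room coordinates when the environment deforms; if
the map encodes the sequence and connectivity of places (a topological
reading), fields should ride the track itself, stretching and shrinking with
it. `morphtrack` implements the analysis that separates these readings on two
purpose-built morphing U-tracks, for computational neuroscientists who want
to run the method on their own position/spike tables or to study its
statistical behaviour on fully synthetic sessions.

## The method

**Track A (accordion U-track).** Ten rigid 40 cm segments; the two arms fold
concertina-style under the equal-angle constraint ∠(1,2) = ∠(3,4) = α (top
arm) and ∠(7,8) = ∠(9,10) = β (bottom arm), while the base (segments 5–6)
stays fixed. Every sample and spike is kept in two frames: planar room
coordinates (x, y) and track coordinates (x_L, y_L), where x_L is arc length
from food well F1 and y_L the lateral offset from the midline. Poses are
indexed by the vertical section (1–12, 9 cm wide) holding each arm's food
well; sections entered by fewer than 3 configurations are dropped (N_V ≥ 3).

For each cell, pooled occupancy-normalized rate maps (3 × 3 cm bins, rates
averaged over random grid shifts of up to half a bin, no other smoothing;
samples below 3 cm/s excluded) are built per section group and frame. The
activity vectors u_i (planar) and v_i (linear) of section pairs give a
Pearson correlation matrix C_ij over bins that were visited in both groups
and hold at least one spike. Subdiagonal averages

    r_d = ⟨ C_{i,i+d} ⟩

trace stability against geometric dissimilarity d; Welch two-sample t-tests
compare the linear and planar entry sets at each d, and cells with fields on
the static base serve as the control.

**Track B (protrusion-flip track).** Eleven segments; three of them form a
rectangular protrusion that flips between the arms across two run sessions.
Four linearized correlations adjudicate between hypotheses: **Flip** (rates
on the physical protrusion segments against the same segments after the
flip), **Distance** (against the bins at equal arc distance from the well),
**Segment** (the protrusion's center segment against the straight section it
projects onto), and **Rescaled** (the protrusion span affinely compressed
onto its replacing section before correlating). Means are compared with
Mann–Whitney u-tests and one-way ANOVA with Tukey–Kramer post-hocs over
cells whose peak rate clears 2 Hz.

**Synthetic sessions.** The generator reproduces the task (alternation runs
of ~34 s between wells, 40 pose moves per session executed during reward
pauses) and simulates single-field place cells with Gaussian tuning
(default peak 15 Hz, baseline 0.1 Hz, σ = 10 cm) and Poisson spiking, under
four anchorings: `planar` (room point), `linear_fraction` (fixed fraction of
the track's elastic skeleton — fields stretch with local deformations),
`segment_bound` (rides a material segment), and `distance_from_well`.

## Worked example

```python
from morphtrack import AnalysisConfig, run_track_a
from morphtrack.pipeline import simulate_session_a

bundle, _ = simulate_session_a(n_cells=50, anchoring="linear_fraction",
                               n_moves=40, seed=1)
result = run_track_a(bundle, AnalysisConfig(seed=1))
print(result.report())
```

prints (abridged):

```
Track A dual-frame correlation analysis
  cells: 50 (mobile 40, static 10, unclassified 0)
  frame pattern: linear-stable
  d= 2: r_1D=+0.708  r_2D=+0.223  Welch p=3.66e-64
  d= 6: r_1D=+0.699  r_2D=-0.399  Welch p=1.14e-84
  d=10: r_1D=+0.709  r_2D=-0.408  Welch p=9.29e-27
```

The linear-frame correlations hold near 0.70 out to maximally dissimilar
poses while the planar-frame correlations decay below zero: the simulated
fields rode the track, not the room. Running the Track B battery
(`examples/04_track_b_protrusion.py`) under each generator prints

```
linear_fraction      flip=+0.03  distance=+0.13  segment=+0.74  rescaled=+0.98   argmax: rescaled
segment_bound        flip=+0.64  distance=+0.06  segment=-0.05  rescaled=+0.03   argmax: flip
distance_from_well   flip=-0.14  distance=+0.98  segment=-0.39  rescaled=-0.05   argmax: distance
```

— the winning comparison identifies the anchoring that generated the data.
The `examples/` directory holds one short script per capability (geometry,
session generation, each analysis); `morphtrack --help` exposes the same
drivers as a thin command line (`simulate`, `analyze-track-a`,
`analyze-track-b`).

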