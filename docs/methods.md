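# Methods

## Generative model of a gap-junction plaque

A plaque is a smooth planar ribbon imaged across consecutive 50 nm
sections. Its **midline** is a cubic spline through control points,
re-parameterised by arc length `s`. The two membranes' bead strings are
offsets of the midline at `± gap(s, z) / 2` along the local unit normal,
with the **gap profile**

    gap(s, z) = g0 + Σ_b a_b · f_b(z) · exp(−(s − c_b)² / (2 w_b²))

a baseline `g0` plus Gaussian bulges (centre `c_b`, amplitude `a_b`, arc
width `w_b`). `f_b(z)` ramps linearly from 0 at the plaque's first and
last section to 1 at the central section, so a bulge persists smoothly
across several sections, peaking mid-structure; the maximum width of the
structure is therefore exactly `g0 + max_b a_b` (realised at the central
section).

Beads are generated as **docked pairs**: pair positions are laid out along
the arc at mean spacing `bead_spacing_nm` with jitter truncated at ±2 s.d.
(preserving order), and each member receives an independent tangential
offset (s.d. = half the spacing jitter, truncated likewise) and a diameter
drawn uniformly from `bead_diameter_range_nm`. An **orphan run**
`(side, start, length)` deletes the named side's beads (and, by default,
its membrane curve) within the arc interval; the surviving single string is
the generative hemiplaque. Because sections (50 nm) exceed the largest
bead (20 nm), each bead exists in exactly one section.

Rendering: inverted isotropic Gaussian per bead with FWHM equal to the
bead diameter and amplitude `bead_contrast`; membranes as faint dark
curves at 30% of the bead contrast (σ = 0.8 px); a low-frequency
background texture (Gaussian-filtered noise, correlation length
`background_texture_scale_nm`, default 200 nm, s.d. 6 intensity units on a
background at 72% of dynamic range); additive Gaussian pixel noise
(`noise_sd`, must be > 0). All randomness descends from one seed through
`numpy` seed sequences; identical inputs give bit-identical stacks.

### Default study conditions

Defaults emulate the two morphologies the pipeline is meant to separate
and are fixed once (in `fixtures.py`), not tuned per experiment:

| parameter | control_like | pkp2cko_like | rationale |
|---|---|---|---|
| voxel size | 3.5 × 3.5 × 50 nm | same | standard SBF-SEM acquisition geometry |
| baseline gap `g0` | 20 nm | 20 nm | bead centre-to-centre distance of closely packed double strings |
| bulges | none | 1, amplitude 60–80 nm, width 150–300 nm | widened intercellular space up to ~100 nm |
| orphan runs | none | one per plaque, ~20% of arc, random side | hemiplaque burden of the disease-like group |
| bead spacing / jitter | 25 / 3 nm | same | "closely packed" label strings |
| bead diameter | U(10, 20) nm | same | silver-enhancement particle size |
| plaque length | 1.5–2.1 µm | same | plaques spanning hundreds of beads |
| sections spanned | 5–7 of a 7-slice stack | same | plaques traverse multiple 50 nm sections |
| bead contrast / noise s.d. | 120 / 8 (8-bit) | same | high-contrast backscatter puncta, moderate noise |

Cohorts are laid out four plaques per ROI stack in separate horizontal
bands; ROIs alternate LV/RV ventricle labels so stratified comparisons can
be exercised. The generator does **not** emulate other organelles
(mitochondria, desmosomes, myofibrils), section-compression or alignment
jitter, electron-optics effects, or fluorescence channels; passing tests
therefore demonstrate correctness of the measurement chain on clean
double-string geometry with realistic contrast, texture and noise — not
robustness to every confound of real tissue.

## Montage tiling

`render_tiles` cuts a stack into `n` frames along its long lateral axis
with `round(f · W)` shared pixels (`f` the overlap fraction, `W` the tile
extent, chosen as the largest integer for which the tiles fit);
`stitch_tiles` reassembles them by pure translation at the known offsets.
This replaces a feature-based stitching step: synthetic tiles are exact,
so translation at recorded offsets is sufficient.

## Bead detection

Per slice, the intensity-inverted image (normalised to [0, 1]) is filtered
with a scale-normalised Laplacian of Gaussian at 5 scales spanning the
diameter band (σ = d / 2.355 px); the per-pixel maximum over scales is
peak-picked (`threshold` default 0.08), greedily non-maximum-suppressed at
`min_separation_nm` (default 12 nm — deliberately below the 20 nm gap so
both members of a docked pair survive), and refined to sub-pixel precision
by quadratic interpolation. The diameter estimate is 2.355 σ at the argmax
scale. The threshold was calibrated on synthetic fixtures only (blank
noise stacks yield zero detections; beads score ≈ 0.15–0.25, membranes
≈ 0.05). Requires square lateral pixels and a low diameter of ≥ 2 px.

Known limitation: for two dark puncta closer than about the detector
scale, the LoG side-lobes push the two response peaks slightly apart, so
opposing bead centres at a 20 nm gap are localised ≈ 1–2 nm too far from
each other. This propagates into a small positive bias (≈ +5%) of
area-per-length and max width on narrow-gap plaques; it is well inside the
recovery envelope and does not affect pairing or hemiplaque calls.

Evaluation against ground truth uses greedy one-to-one matching by
ascending distance within the same slice (radius 15 nm ≈ one bead
diameter); greedy rather than optimal assignment is order-stable, and at
these densities the two coincide.

## Reconstruction

* **Clustering**: single-linkage connected components in 3D physical
  coordinates (z = slice × 50 nm), link distance 150 nm, minimum 6 beads.
* **Midline**: beads of one cluster-slice are ordered by projection onto
  their principal axis and smoothed with a centred moving average (window
  ≈ n/6, clamped to [5, 15], odd); because the two strings interleave
  along the arc, the average runs between them. When the cloud is strongly
  folded (second/first eigenvalue ratio > 0.1) the ordering falls back to
  the diameter path of the Euclidean minimum spanning tree, which handles
  U- and C-shaped plaques. The smoothed curve is extrapolated 150 nm
  tangentially at both ends: a centred moving average shrinks the curve
  ends by about half a window, and without the extension end beads clamp
  to the terminal vertex and produce spurious width spikes.
* **Sides**: every slice's midline is oriented along the cluster's global
  principal axis (deterministic sign), making side labels consistent
  across slices; side A is the positive-normal side of the signed
  perpendicular offset. Beads with |offset| < 2 nm are assigned by a
  3-nearest-neighbour vote and flagged ambiguous. When ≥ 4 docked pairs
  can be identified (mutual-nearest by arc position), the midline is
  refitted through pair midpoints and sides reassigned — this keeps the
  midline centred across orphan intervals where the plain moving average
  would drift toward the surviving string.
* **Polylines and inner space**: per-side polylines connect bead
  centroids in arc order (no smoothing; a side with < 2 beads contributes
  none). The inner-space polygon trims both polylines to their common arc
  interval, closes the ring with straight end caps, and takes the polygon
  (shoelace) area. A self-intersecting ring is repaired by zero-width
  buffering and keeping the largest simple component, flagged in the
  output. Plaque ends covered by only one string are excluded from area
  but remain hemiplaque evidence. Slices with < 4 beads are skipped with
  a logged warning.

## Morphometrics conventions

* Per-plane length is the midline arc over the trimmed overlap; area per
  length is reported in nm (nm²/nm).
* The per-plaque average of area-per-length is an **unweighted** mean over
  planes; plane counts are reported so a length-weighted reanalysis is
  possible.
* Max width is sampled at ≤ 5 nm arc steps as the distance between
  equal-arc-position points of the two polylines (for locally parallel
  curves this equals the perpendicular distance); the plaque value is the
  maximum over planes — a supremum over the structure, not over beads.
* Pairing: mutual-nearest by arc position, accepted when |Δs| ≤ 0.6 × the
  pair spacing (estimated as twice the median consecutive arc spacing of
  the interleaved cloud; scale-free rather than a fixed nm value) and the
  Euclidean separation is ≤ 120 nm.
* Hemiplaque calling: within each plane and side, maximal runs of
  consecutive unpaired beads with ≥ 3 members spanning ≥ 100 nm (both
  thresholds configurable; the defaults are ~2× the bead spacing so a
  single missed detection cannot fabricate or split a call). Segment
  length = run span + half a bead spacing at each end. Per-plaque totals
  sum segments across planes, capped at the plane length; the fraction is
  100 × total hemiplaque length / total plaque length.
* Ground-truth records report hemiplaque intervals at the arc level (each
  orphan run counted once); recovered records sum per-slice segments.
  The *fractions* coincide (both reduce to the arc fraction covered), and
  are what recovery is judged on.
* Cohort statistics: percentage of plaques with ≥ 1 hemiplaque, pooled
  hemiplaque length, and pooled length fraction per (genotype, ventricle)
  group.

## Statistical protocol

Normality gate: Shapiro–Wilk OR Kolmogorov–Smirnov; the KS test is against
a normal with estimated mean/s.d. and therefore Lilliefors-corrected by
default (naive KS behind a flag for auditing). Zero-variance samples are
flagged degenerate and routed nonparametric. Both groups normal →
two-sided pooled-variance Student's t (Welch behind a flag); otherwise
two-sided Mann–Whitney U — exact by full enumeration of rank assignments
(mid-ranks under ties) when both n ≤ 8, tie-corrected normal approximation
with continuity correction above. α = 0.05; no multiple-testing
correction (reports carry the comparison count). Box summaries use
linear-interpolation quartiles.

## Pipeline and reproducibility

One global seed fans out to per-stage seeds by fixed offsets. Every run
writes a manifest with a config snapshot, SHA-256 checksums of all
outputs, package version and timestamps; re-running an identical config
reproduces checksum-identical tables. Tables are UTF-8 CSV with units in
headers; nested structures are JSON; stacks are multi-page TIFF with voxel
sizes in the TIFF tags and a JSON sidecar.

## Problem sizes

The shipped validation studies use ROI stacks of 4 plaques × 7 sections at
3.5 nm pixels (≈ 5 Mpx per stack), cohorts of 20 plaques per group for
parameter recovery, and 100 simulated replicates at n = 20/group for the
directional-replication study; the replication study evaluates generative
ground-truth metrics (the image-based chain's fidelity is established
separately by the recovery study), which keeps it to a couple of minutes.

## Known limitations

* The generator's beads mark membrane positions directly; the real 2–4 nm
  intercellular cleft and label displacement by antibody geometry are not
  modelled — area-per-length here measures bead-string separation.
* Detection bias for apposed puncta (above) slightly inflates narrow-gap
  widths; at 3.5 nm pixels it is bounded by ≈ 2 nm.
* Plaques are assumed aligned across sections (no drift correction) and
  roughly ribbon-like; heavily branched or closed-loop plaques are out of
  scope.
* Group comparisons pool plaques (hearts/ROIs are retained as columns for
  hierarchical reanalysis, but no mixed-effects model is provided).
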