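# Methods

## The spatial-dispersion model

The package treats cytoskeletal organization as a question about the joint
distribution of two per-fiber quantities: *where* a stress-fiber edge sits
relative to the nucleus, and *which way* it points.  Each detected edge
contributes one point (D_avg, A) — mean Euclidean distance from the edge's
pixel centroid to all detected nucleus centroids, and the edge's axis angle
in [0°, 180°).  In an organized cell the fibers are parallel and arranged
coherently around the nucleus, so the points concentrate in few cells of a
2D histogram; in a disorganized cell they spread out.  Shannon entropy of
the cell occupancy probabilities, normalized by its maximum ln(n), turns
this into a score on [0, 1]:

    etp = Σ_cells −p ln p   (0·ln 0 := 0),     dsp = etp / ln(n).

The normalization ratio is independent of the logarithm base; natural
logarithms are used throughout.  dsp is a *distributional* statistic: it is
invariant to the processing order of segments and to any permutation of the
feature points.

## Edge detection

Canny stages with one non-standard element, the threshold rule:

* Gaussian smoothing, sigma = **1.4 px** on the 512×512 frame (standard
  Canny smoothing scale; preserves fibers a few pixels wide).
* 3×3 Sobel stencils (cross-correlation form, reflective borders);
  magnitude G = √(Gx²+Gy²).
* **Adaptive dual thresholds**: T_max = M + 2S and T_min = T_max/T, where
  M and S are the mean and *population* standard deviation of G over all
  pixels (no sample correction — the convention for image statistics) and
  the reduction ratio defaults to **T = 2**, the canonical Canny high:low
  ratio.  This self-calibrates edge screening across images with different
  staining intensity.
* Non-maximum suppression with direction quantized to 4 sectors; plateau
  ties are broken asymmetrically (≥ toward one neighbor, > toward the
  other) so edges stay one pixel thin along the gradient direction.
* Hysteresis: pixels ≥ T_max seed; candidates ≥ T_min survive if their
  8-connected candidate component contains a seed.

**Featureless guard.**  A purely relative threshold cannot distinguish a
structureless noisy field from a structured one — both scale the same way.
For smoothed Gaussian noise the gradient magnitude has a Rayleigh-like
distribution with S/M ≈ 0.52, and T_max = M+2S then sits inside the noise
tail: spurious ridge chains percolate across the frame.  Structured
micrographs have heavy-tailed magnitudes (edges rare and strong; the
weakest single-filament fixture measures S/M ≈ 2.1).  `canny_edges`
therefore returns an empty map when S ≤ M, which also covers the constant
image (M = S = 0).  The guard is scale-invariant, so it holds at any noise
amplitude and never fires on an image containing resolvable fibers.

Edge components are 8-connected (diagonal fiber edges fragment under
4-connectivity) and components shorter than **min_edge_length = 10 px**
(~2 % of the frame width) are discarded as noise specks.  Orientation is
the principal axis of the component's pixel coordinates (row axis negated
so angles follow math convention, counterclockwise from horizontal),
folded into [0, 180).  Exactly horizontal edges are reported as 0° and
included; a fiber population genuinely excludes at most a measure-zero set
of angles, so the closed endpoint is harmless.

## Nucleus detection

The composite is converted to HSV (hue in degrees); pixels inside the blue
bracket **hue ∈ [190°, 270°], S ≥ 0.25, V ≥ 0.20** (covers DAPI/Hoechst
renderings, excludes cyan-green bleed; fully configurable) are grouped
into 8-connected regions, regions under **min_region_area = 50 px** are
dropped, and each survivor contributes its area centroid.  Centroids are
robust to irregular nuclear shapes, and merged touching nuclei still give
a usable reference point; no watershed splitting is attempted.  If no
region survives, the end-to-end computation raises a data error rather
than emitting distance features with no referent.

## Histogram and numerical choices

* Grid default **8 distance × 8 angle bins** (n = 64): balances resolution
  against occupancy for the tens-to-hundreds of segments a 512×512 field
  yields.
* Distance axis spans [0, max observed D_avg] per image (the maximum lands
  in the top bin), making dsp resolution-independent; a fixed-range mode
  (`distance_range_mode: fixed`, default d_max = the frame diagonal 724)
  is available when absolute cross-image comparability matters.  The angle
  axis always spans [0°, 180°).
* Degenerate cases: an all-zero distance set uses a unit range (all points
  in the first bin); empty cells contribute 0 to the entropy; dsp is
  clipped to [0, 1] against rounding at the ln(n) boundary.
* Images are resized to 512×512 by bilinear interpolation without
  preserving aspect ratio (the original geometry is kept as metadata);
  nearest-neighbor would alias thin fibers.  Pixels are held as float in
  [0, 1] whatever the native bit depth, so all thresholds are
  depth-independent.

## Group comparison

Per-image dsp is the unit of analysis.  Two groups are compared with the
unpaired **pooled-variance Student t test** (not Welch), df = n_a+n_b−2,
two-sided p, with means ± SEM reported per group.

## Synthetic fixtures

`generate_fixture` emulates a phalloidin/DAPI composite: straight
anti-aliased filament segments (signed-distance coverage profile — hard
rasters would create double staircase edges; the soft profile mimics the
microscope point-spread) of 40–100 px length and 3 px width at intensity
0.8 in the green channel; filled blue disks (intensity 0.9) for nuclei;
background 0.05 plus additive Gaussian noise (sd 0.02), so the adaptive
thresholds always see nontrivial statistics.  Orientations are sampled as
*axial* data: von Mises on doubled angles, then halved — the correct
circular model for undirected fibers, with concentration κ ranging from 0
(uniform) to effectively aligned.  Filaments are placed uniformly with
bounded retries, rejecting placements that cross a nucleus; ground truth
(endpoints, angles, nucleus centers) is returned alongside every image and
generation is byte-deterministic in the seed.

`ordered_vs_random_pair` produces matched organization extremes: the
ordered member puts equally many filaments, all at the mode orientation,
at regular angular positions on a ring at fixed distance from the nucleus
(one distance bin, one angle bin by construction); the disordered member
uses uniform orientations and placement.

What the fixtures do *not* emulate: curved fibers, fiber crossings with
realistic intensity addition, PSF stacks, shot noise, uneven illumination,
or textured cytoplasm background.  Passing tests therefore demonstrate
correctness of the measurement chain and the direction of the
order/disorder contrast, not performance on real micrographs with those
confounds.

## Problem sizes and determinism

The validation battery uses 10 ordered/disordered pairs for the
discrimination study, 20 isolated-filament fixtures for geometry recovery,
20 seeds per κ ∈ {0, 2, 8, 32} for the monotonicity check, and 50 seeded
random fields for the threshold oracle — sizes at which every check runs
in seconds while leaving the statistical conclusions unambiguous (the
ordered/disordered separation is ~60 pooled SEMs).  The pipeline contains
no randomness: all stochasticity lives in fixture generation and is
seed-derived.

## Known limitations

* Edge (outline) detection, not ridge/centerline detection: each thick
  fiber contributes its outline as one or two segments; sub-pixel
  localization and curvature analysis are out of scope.
* D_avg uses the segment *centroid* as the edge's representative point;
  for strongly curved or very long edges the centroid may sit off the
  fiber.  The nearest-pixel alternative was rejected as unstable for long
  fibers.
* The distance axis's per-image range makes dsp comparable across
  magnifications but means a lone distant outlier can compress the
  remaining occupied bins; use the fixed-range mode when that matters.
* Touching nuclei are not split; their merged centroid shifts distance
  features slightly.
* dsp saturates: once points occupy all cells roughly uniformly, further
  disorganization cannot raise the score.
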