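# actin-dispersion

Entropy-based quantification of F-actin stress-fiber organization in
fluorescence micrographs.

Vascular smooth muscle cells (and many other cell types) reorganize their
actin cytoskeleton under disease conditions: ordered, parallel stress-fiber
arrays give way to fragmented, randomly oriented filaments — for example in
CADASIL, where NOTCH3 variants disorganize the VSMC cytoskeleton.  Visual
scoring of phalloidin/DAPI composites is subjective; this package computes a
single reproducible disorder score, the **spatial dispersion** `dsp ∈ [0, 1]`,
for each micrograph, and compares experimental groups with an unpaired
Student *t* test.

## The statistic

For an RGB micrograph (actin = green, nuclei = blue), resized to 512 × 512:

1. **Edge detection.**  Stress-fiber edges are outlined with a Canny
   pipeline (Gaussian smoothing, 3 × 3 Sobel gradients
   G = √(Gx² + Gy²), non-maximum suppression, dual-threshold hysteresis)
   whose thresholds adapt to each image's gradient statistics:

       T_max = M + 2S,     T_min = T_max / T

   with M, S the mean and standard deviation of G over all pixels and
   T ≥ 1 the reduction ratio (default 2).  Edge components shorter than
   `min_edge_length` pixels are discarded.
2. **Nucleus reference.**  Blue nuclear regions are segmented in HSV space
   (configurable hue/saturation/value bracket); small regions are filtered
   out and each region contributes its area centroid, a "blue center".
3. **Feature points.**  Each surviving edge *i* becomes a point
   (D<sub>avg,i</sub>, A<sub>i</sub>): the mean Euclidean distance from the
   edge centroid to all blue centers, and the edge's principal-axis angle
   to the horizontal, in [0°, 180°).
4. **Entropy.**  The points are binned on an equal-width 2D grid of
   n = n_dist × n_angle cells (default 8 × 8) with occupancy probabilities
   p, and

       etp = Σ −p·ln(p),      dsp = etp / ln(n)  ∈ [0, 1].

   `dsp → 0` for parallel, equidistant fibers (all points in one cell);
   `dsp → 1` for a maximally disorganized cytoskeleton.

A seeded synthetic-micrograph generator (anti-aliased filaments with
von Mises–distributed orientations, blue disk nuclei, Gaussian noise)
provides ground truth for every stage, so the whole pipeline is testable
without any imaging data.

## Worked example

Generate a battery of synthetic fixtures (3 ordered / 3 disordered pairs)
and score them:

```sh
actin-dispersion fixtures make demo/fx --n-pairs 3
actin-dispersion run demo/fx -o demo/all.csv
```

The results table (path, n_points, n_nuclei, etp_nats, dsp):

```
                       path  n_points  n_nuclei  etp_nats       dsp
  demo/fx/disordered_00.png        32         1  3.059489  0.735652
  demo/fx/disordered_01.png        35         1  2.941031  0.707168
  demo/fx/disordered_02.png        26         1  2.918058  0.701645
     demo/fx/ordered_00.png        52         1  0.562335  0.135213
     demo/fx/ordered_01.png        52         1  0.656454  0.157844
     demo/fx/ordered_02.png        52         1  0.631978  0.151959
demo/fx/single_filament.png         1         1  0.000000  0.000000
```

Ordered fields (parallel fibers on a ring at fixed distance from the
nucleus) concentrate their (distance, angle) points in one histogram cell
and score dsp ≈ 0.15; matched disordered fields spread over the grid and
score ≈ 0.72.  Splitting the table into two CSVs and comparing:

```sh
actin-dispersion compare demo/ordered.csv demo/disordered.csv
# t = -45.2143, df = 4, p = 1.431e-06; means 0.1483 ± 0.0068 vs 0.7148 ± 0.0105
```

From Python, the same pipeline is a scikit-learn transformer:

```python
from actin_dispersion import ActinDispersion, FixtureSpec, generate_fixture

images = [generate_fixture(FixtureSpec(seed=s))[0].pixels for s in range(4)]
dsp = ActinDispersion(n_dist_bins=8, n_angle_bins=8).fit_transform(images)  # (4, 1) column
```

`ActinDispersion(...).compute(image)` returns the full per-image record
(entropy, histogram, feature points, parameter provenance), and
`actin-dispersion inspect IMG --debug-dir d/` writes edge/nucleus overlay
PNGs plus per-segment and per-nucleus tables.

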