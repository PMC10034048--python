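# Methods

This note documents the models, parameter choices and numerical decisions
behind `trihinge`, and what the synthetic validation does and does not
establish about real cortical data.

## Problem setting and assumptions

A 3-hinge is the junction of three gyral crests. The package assumes the
hinge *vertex* annotations (3-hinge junction vertices, 2-hinge crest
vertices) are given — on real data they come from an upstream gyral-crest
graph extraction; on synthetic data they are ground truth. Everything
downstream depends only on local intra-subject geometry: distances are
ambient Euclidean in the surface's native coordinate frame, no registration
or resampling is performed, and hemispheres are processed independently.

Vertex indices are 0-based everywhere. Plain-text annotation lists may
declare `index_base=1` in a header line and are converted on read.

## Region labeling

`label[v] = 1` iff v lies within R₁ = 6 mm of a 3-hinge vertex or
R₂ = 2 mm of a 2-hinge vertex (set union; a vertex satisfying both is
labeled once). "Spherical neighborhood" is read as an ambient Euclidean
ball, not a geodesic disk: the radii are small relative to cortical
curvature and a sphere of radius R is an ambient object. A KD-tree
accelerates the query; correctness is defined by (and tested against) the
brute-force all-pairs rule. Expansion runs over all surface vertices, not
only crest vertices.

## Feature aggregation and blocking

The per-vertex network input is `[a, b1, …, b15]`, the vertex's own
morphometry value followed by its k = 15 nearest neighbors' values in
ascending distance order. Ties at equal distance (common on lattice-like
meshes) break to the lower vertex index, and squared distances are
recomputed from coordinates so that symmetric neighbors compare exactly
equal — the output is fully deterministic. Min–max normalization to [0, 1]
is per feature, per subject-hemisphere, over real (non-pad) vertices only;
it happens before blocking so padded slots stay exactly 0 and never enter
the statistics. A constant feature normalizes to all zeros with a warning.

Rows pad with zeros to the next multiple of 64·64 = 4096 and tile
row-major into `(64, 64, channels)` blocks; an explicit slot↔vertex index
map makes the tiling invertible, so the (arbitrary) choice of native file
order for block layout cannot affect any per-vertex result. Multi-feature
runs produce one tensor per feature over a shared index map.

## Segmentation network

A symmetric U of `depth` levels (default 5). Per level: conv3×3 → BN →
ReLU → dropout → conv3×3 → BN → ReLU, then a squeeze-and-excitation block;
encoder levels end in 2×2 max pooling with channel doubling, decoder levels
start with a learned 2×2 transposed convolution halving channels followed
by skip concatenation. A 1×1 two-channel head with channel softmax produces
the class distribution (two channels rather than one sigmoid unit, matching
the softmax head). The plain U-net variant omits the SE blocks and is
otherwise layer-identical, which the parameter-count audit in the tests
verifies against the closed form `2·C·⌊C/r⌋ + C + ⌊C/r⌋` per SE block. The
pre-fusion variant gives each input feature its own conv–BN–ReLU stem and
concatenates stem outputs before the first level.

Training minimizes the soft Dice loss on the foreground probability,
`1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1.0 smoothing; padding slots are
masked out of every sum (the zero-padding convention says nothing about the
loss, so masking is this package's choice — it prevents the network from
being rewarded for predicting background on artificial slots). Optimization
is RMSprop (ρ = 0.9, eps = 1e−7) at lr₀ = 0.05 with per-epoch exponential
decay; the decay factor is not pinned by the published schedule beyond
"exponential per epoch", so the default is 0.96 and it is exposed in the
config. Batch size 40, 150 epochs, BN momentum 0.6 (Keras convention:
`running = 0.6·running + 0.4·batch`, eps = 1e−3), dropout 0.2 placed once
between the two convolutions of each double-conv block. Weights initialize
He-normal from a seeded generator; shuffling and dropout draw from
derived generators, so a fixed seed reproduces training exactly.

The engine itself (im2col convolutions, hand-derived backward passes,
float32 throughout) lives in `trihinge.nn`; gradient correctness is
checked against finite differences per layer and through the whole graph.
Note that conv biases feeding directly into BN have ~zero true gradient
(BN removes constant shifts), which is expected, not a defect.

### Desk-scale preset

Tests and the acceptance script run a scaled-down configuration chosen as
the package's default small-problem setting: 120×120 mm sheets at 1 mm
spacing (14,400 vertices → 4 blocks, exercising the zero-pad path), depth
4, base 8 channels, SE reduction r = 8 (r may not exceed the first-level
channel count, since ⌊C/r⌋ ≥ 1 is required), ≤ 30 epochs, batch 8. The
full-scale preset (576×576 sheet = 331,776 vertices = exactly 81 blocks,
depth 5, base 64, r = 24, 150 epochs, batch 40) is available as
`--preset paper`.

## Weighted mean shift

The offset is computed with the radial profile
`g(u) = u/(√(2π)s³)·exp(−u²/2s²)` on the scalar normalized distance
`u = ‖Xᵢ−X_m‖/h`. The underlying kernel definition applies a 1-D
derivative-of-Gaussian to a vector argument; evaluated literally it is
dimensionally ill-defined, and with the isotropic bandwidth H = h²I the
standard reading is a radially symmetric profile on ‖·‖ — that reading is
implemented, documented here rather than silently assumed. The weight
function is likewise only motivated ("closer vertices matter more"), not
specified; the default is `w(Xᵢ) = exp(−‖Xᵢ−X_m‖²/2h²)`, recomputed against
the current center each iteration, with `uniform` recovering the classical
algorithm and a `flat` in-sphere kernel option reproducing the original
sample-mean offset (both are cross-checked in tests). Defaults: h = 6 mm
(the region radius), s = h/2, convergence when ‖M_h‖ < 1e−3 mm, ≤ 200
iterations. `g(0) = 0`, so a seed coinciding with all points is a flagged
degenerate case returning a zero offset.

### Seeding and mode screening

Ground-truth region labels are one *connected* set: R₁ = 6 mm junction
disks are joined by continuous R₂ = 2 mm crest bands. Seeding one mean
shift per connected component therefore cannot produce one centroid per
junction; the component framing had to be extended. `find_centroids`:

1. splits labeled vertices into mesh-connected components and drops those
   below `min_region_size` (5 vertices);
2. seeds every component with a deterministic greedy subsample of its
   labeled vertices at h/2 spacing and iterates all seeds (vectorized,
   restricted to the component's points);
3. screens converged modes by **label occupancy** — the fraction of all
   surface vertices within h of the mode that carry the label. At a true
   junction the h-ball lies inside the fully labeled R₁ disk (occupancy
   ≈ 1.0); on a crest band the ball is mostly unlabeled (≈ 2·R₂·2h /
   πh² ≈ 0.4). The threshold 0.6 sits between these two regimes by
   geometry, not by tuning; if no mode passes, the strongest mode is kept
   so memberships still partition the points;
4. merges surviving modes by single linkage at `merge_radius` (h/2),
   averaging with occupancy weights — single linkage makes the mode count
   provably non-increasing in the merge radius;
5. assigns every labeled vertex to its nearest surviving centroid.

## Evaluation

Precision, recall and F1 are per-vertex percentages; undefined ratios
(empty prediction or empty truth) report as 0 with the convention noted.
PreE matches each *reference* centroid to its nearest predicted centroid
and averages the distances — missing a hinge is the failure that matters —
and a symmetric variant is also available since the matching direction is
not fixed by the definition; an empty prediction reports as missing.
Default aggregation over subjects is macro (per-subject means, F1 averaged
as F1): published region F1 values differ slightly from the harmonic mean
of the published P and R, which is the signature of per-subject averaging.
Micro (pooled confusion counts) is implemented and tested as well. The
gender analysis is the point-biserial Pearson correlation between
per-subject identification accuracy (F1 by default) and 0/1 gender, with
the two-sided t-based p-value; no multiple-testing correction is applied
across feature combinations, mirroring how such tables are usually
reported raw.

## Synthetic generator

The generator emulates exactly the structure the pipeline depends on: a
surface with a crest network whose triple junctions are hinges, plus
morphometry statistically coupled to crest geometry. It is a 2.5-D
height-field sheet, not a closed cortical surface: all operations used are
local (KNN, metric balls, blocking, mean shift), and on a sheet the ground
truth is exact and analytically checkable. Crest skeletons come from a
planar graph — Voronoi edges of triangular-lattice seeds (hexagonal cells,
degree-3 junctions), blue-noise random seeds (generic Voronoi), or a
direct triangular lattice (degree-6 junctions) — clipped to an interior
box whose margin (8 mm ≥ h) guarantees every junction's h-ball lies on
the sheet. Height is `ridge_height·exp(−d²/2w²)` of the distance d to the
skeleton (default amplitude 5 mm, crest width w = 2.5 mm, roughly gyral
scale); vertex jitter and map noise scale with `noise_sd` (0.25 mm
default). Maps: sulc = −height + noise; curv = −½∇²height (positive on
crests, negative on flanks); thickness = 2.5 mm + 0.6 mm·(height/max)
(gyri thicker); area from incident triangle areas; volume = area ×
thickness. Labels and centroids always derive from the noiseless skeleton,
so planted junction counts are invariant to noise. Cohorts alternate
genders and shift `ridge_height` by `gender_effect` for one group, with
per-subject seeds derived from the base seed by a fixed counter scheme.

What passing synthetic tests does **not** show: robustness to real
cortical spectral statistics, topological noise, inter-subject variability
in crest geometry, or the error characteristics of upstream crest-graph
extraction. The synthetic results establish correctness of the machinery
and learnability of the planted signal, not published-accuracy claims on
restricted cohorts.

## Known limitations

- Geodesic distances are not used anywhere (neighborhoods, labeling); on
  highly folded real surfaces an ambient ball can bridge sulcal banks.
- The mean-shift weight function is a documented default, not an inference
  of any reference implementation.
- The blocking destroys 2-D spatial adjacency beyond runs of 64 vertices;
  the network therefore learns predominantly channel-wise (neighborhood
  vector) structure, which is also what makes the block layout choice
  harmless.
- Training at the full 64-channel, 150-epoch scale on CPU is possible but
  slow; the desk preset is the supported test configuration.
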