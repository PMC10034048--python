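# trihinge

Fast identification of cortical **3-hinges** — the junctions where three
gyral crests meet — from surface-based morphometry.

3-hinges are compact, individually variable folding landmarks of the human
cortex: they carry thicker cortex and denser axonal wiring than ordinary
gyri, and their layout differs between individuals and between sexes. The
classical way to find them builds an explicit gyral-crest graph per
hemisphere (watershed plus tree marching), which is accurate but slow. This
package implements the learning-based alternative: segment 3-hinge *regions*
directly from per-vertex morphometry maps with a squeeze-and-excitation
U-net, then localize each region's *centroid* with a weighted mean shift.
It is aimed at researchers processing FreeSurfer- or GIfTI-style cortical
surfaces who need hinge landmarks at cohort scale.

## Method

Given a triangulated hemisphere surface with `n` vertices and a morphometry
map (sulc, curv, thickness, area or volume):

1. **Feature aggregation.** Each vertex `a` gets the 16-vector
   `[a, b1, …, b15]` of its own value and its k = 15 nearest neighbors'
   values (Euclidean distance, ascending). Features are min–max normalized
   to [0, 1] per subject-hemisphere, zero-padded to the next multiple of
   64·64 = 4096 vertices, and tiled into `(64, 64, 16)` blocks — e.g. a
   330,000-vertex cortex pads to 331,776 = 64·64·81 and yields 81 blocks.
2. **Region segmentation.** A 5-level U-net with squeeze-and-excitation
   channel gating (reduction ratio r, default 24) after every double-conv
   block maps each block to a two-class softmax field. Training minimizes
   the soft Dice loss with RMSprop (lr₀ = 0.05 decayed exponentially per
   epoch, batch 40, batch-norm momentum 0.6, dropout 0.2); padded slots are
   masked out of the loss. Reference labels mark every vertex within
   R₁ = 6 mm of a 3-hinge vertex or R₂ = 2 mm of a 2-hinge (crest) vertex.
   A multi-feature variant scales each input feature with its own
   conv–BN–ReLU stem and concatenates the stems before the U.
3. **Centroid extraction.** Within each predicted region, candidate
   centroids X_m iterate `X_m ← X_m + M_h(X_m)` with the weighted offset

       M_h(X_m) = Σᵢ g(‖Xᵢ−X_m‖/h) · w(Xᵢ) · (Xᵢ−X_m) / Σᵢ g(‖Xᵢ−X_m‖/h) · w(Xᵢ)

   where `g(u) = u/(√(2π)s³)·exp(−u²/2s²)` is the radial
   derivative-of-Gaussian profile, `w(Xᵢ) = exp(−‖Xᵢ−X_m‖²/2h²)` weights
   points near the current center, and the bandwidth matrix is isotropic
   (H = h²I) with h = 6 mm, the 3-hinge region radius. Converged modes are
   screened by label occupancy and merged within h/2.

Because the cohorts used in published work are access-restricted, the
package ships a first-class synthetic generator: seeded 2.5-D height-field
sheets whose gyral crest network is an explicit planar graph, so every
triple junction — and therefore every 3-hinge — is known exactly, and
sulc/curv/thickness/area/volume are coupled to ridge geometry the way real
maps are to gyri. The synthetic path writes the same file formats the
real-data path reads.

The neural network (convolutions, batch norm, SE gating, pooling,
transposed convolutions, Dice loss, RMSprop — forward and backward) is
implemented in numpy inside `trihinge.nn` and runs on a single CPU.

## Worked example

```python
from trihinge import (SynthConfig, generate_subject, expand_regions, LabelingConfig,
                      find_centroids, MeanShiftConfig, centroid_pre)

subj = generate_subject(SynthConfig(seed=1, grid_shape=(120, 120), n_cells=12))
print(f"vertices: {subj.surface.n_vertices}, planted 3-hinges: "
      f"{len(subj.annotation.three_hinge_centroids)}")

labels = expand_regions(subj.surface, subj.annotation, LabelingConfig(R1=6.0, R2=2.0))
print(f"3-hinge region vertices: {int(labels.sum())} "
      f"({100 * labels.mean():.1f}% of the sheet)")

cs = find_centroids(labels, subj.surface, MeanShiftConfig(h=6.0))
pre = centroid_pre(cs.centroids, subj.annotation.three_hinge_centroids)
print(f"recovered centroids: {cs.n_centroids}, PreE = {pre:.2f} mm")
```

prints

```
vertices: 14400, planted 3-hinges: 21
3-hinge region vertices: 2822 (19.6% of the sheet)
recovered centroids: 21, PreE = 1.50 mm
```

i.e. on a 120×120 mm sheet carrying 21 planted crest junctions, the
R₁/R₂ expansion labels 19.6 % of vertices, and mean shift recovers all 21
centroids with a mean prediction error (PreE — Euclidean distance between
predicted and true centroids) of 1.5 mm, a quarter of the region radius.

The full pipeline — generate, label, features, train, predict, centroids,
evaluate — runs from the command line:

```bash
trihinge run --preset desk --seed 0 --out runs/demo
cat runs/demo/evaluation/report.json
```

`--preset desk` is a small configuration (14,400-vertex sheets, an 8-channel
depth-4 network); `--preset paper` selects full scale (331,776 padded
vertices per hemisphere, 81 blocks, a 64-channel depth-5 network, 150
epochs).

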