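# Methods

`cellasr` implements a two-stage pipeline for 3D fluorescence microscopy
stacks of organisms with stereotyped anatomies (the motivating case is the
newly hatched L1 *C. elegans* larva, whose 558 cells occupy nearly
invariant positions): instance segmentation of densely packed nuclei, and
assignment of a unique identity to every segmented cell.

## Segmentation: displacement-vector-field regression

### The displacement vector field

For an instance mask with background region Φ, each voxel *i* at
coordinates (x<sub>i</sub>, y<sub>i</sub>, z<sub>i</sub>) is assigned

d⃗<sub>i</sub> = (x<sub>i</sub>−x′<sub>i</sub>, y<sub>i</sub>−y′<sub>i</sub>, z<sub>i</sub>−z′<sub>i</sub>),

the offset to its nearest background voxel (x′,y′,z′); background voxels
carry (0,0,0). The per-voxel L2 norm of this field is exactly the
Euclidean distance transform of the foreground, so the field carries the
distance map's information plus a direction that flips sign across the
interface between touching cells — the feature that lets a regressor
separate cells whose intensity boundary is invisible.

Conventions (the source data leaves these open; they are fixed here once
and tested):

* grids are indexed (z, y, x); field channels are ordered (dx, dy, dz);
* equidistant background voxels are resolved to the smallest z-major
  linear index — implemented exactly by enumerating all integer offsets
  of the known (squared) EDT radius rather than trusting any library's
  unspecified tie-break;
* the region outside the volume is not background (crops of larger
  stacks continue foreground across borders), so cells touching the
  border point inward; a caveat for border cells.

### Network and loss

A 3D U-Net-style encoder–decoder regresses the 3-channel field from a
1-channel intensity cube. The full-scale configuration (5 levels,
32/64/128/256/512 channels, 80×128×128 cubes) is expressible via
`segnet.published_config()`; the default desk-scale configuration used by
the tests is 3 levels, 16/32/64 channels, 16×32×32 cubes, which a single
CPU trains in minutes. The network is implemented directly on numpy with
a small reverse-mode tape (im2col GEMM convolutions, max pooling, nearest
upsampling, skip concatenation) and an Adam optimizer (lr 2·10⁻³ for the
desk-scale runs); gradients are verified against finite differences in
the test suite.

The loss is L = ω₁L_d + ω₂L_r with ω₁ = 7, ω₂ = 1:

* L_d = (1/3N) Σᵢ ‖d⃗ᵢ_pred − d⃗ᵢ_gt‖² — mean squared displacement error;
* L_r = 1 − mean cosine similarity, computed over voxels where both
  vectors have norm > 10⁻⁸. The cosine is undefined at the zero vector;
  excluding (rather than epsilon-padding) background avoids biasing it
  toward arbitrary directions.

Training samples cubes at random origins from the training volumes
(serving as crop augmentation); inference partitions the volume on a
regular grid (configurable overlap, overlaps averaged). Intensities are
min–max normalized per volume.

### Post-processing

Predicted field → distance map (L2 norm) → seed cores {dist > t_seed}
labeled by connected components (components < min_size voxels dropped) →
marker-controlled watershed on the negated distance map restricted to
{dist > t_fg}. Defaults t_seed = 2, t_fg = 0.5, min_size = 9,
connectivity 26 suit ground-truth-quality distance maps of nuclei with
2–6 voxel radii. Regressed distance maps systematically undershoot the
true depth (regression to the mean), so for network outputs the seed
threshold is better selected on an annotated validation volume;
`postprocess.select_postprocess_params` grid-searches t_seed and
min_size against validation instance F1. Seed labels are deterministic
(ordered by minimum linear index).

## Recognition: statistical atlas + iterative matching

### The atlas (ASP / SPV / TSV)

From S identity-annotated centroid point sets:

* **ASP** — iterate: affine-align every sample to the current ASP,
  average corresponding cells, then apply the pointwise average of the
  inverse alignment transforms to the result. The literal "subtract the
  mean residual of the aligned samples" formulation is an algebraic
  no-op (that mean *defines* the new ASP), so the bias toward the seed
  sample is removed barycentrically instead: at convergence the mean
  affine from the ASP to the samples is the identity, i.e. the ASP sits
  at the pose barycenter of the population. Convergence: max movement
  < 10⁻³ × body length, ≤ 20 iterations. A final pass maps every sample
  to the converged ASP with a piecewise-affine (PWA) transform and
  averages, which tightens the elongated-axis statistics relative to a
  single global affine.
* **SPV** — per-cell, per-axis standard deviation σ_m of the PWA-mapped
  positions (sample s.d., masked over samples missing the cell; cells in
  < 2 samples get the global median).
* **TSV** — per-cell mean chi-square distance γ_m between the shape
  context of the ASP cell and the shape contexts of the corresponding
  cells in the PWA-mapped samples.

Shape contexts are log-polar histograms of neighbouring centroids:
R = 5 shells log-spaced in [2, 100] voxels × (6 azimuth × 2 polar)
sectors, normalized to unit mass, computed in the point set's PCA body
frame so atlas and subject descriptors share an orientation convention.
Chi-square distance is ½Σ(a−b)²/(a+b+ε).

The PWA transform partitions points along the longest PCA axis into
equal-width segments (default 8, capped at one per ~25 correspondences
so small point sets degrade to a global affine), fits a least-squares
affine per segment with 20% overlap, and blends neighbouring affines
linearly between segment centres, giving a continuous map.

### Matching pipeline

1. **Centroids** of the labeled instances form the subject point set;
   the ASP is the target.
2. **PCA alignment**: centre, rotate principal axes onto principal axes,
   scale per axis by the singular-value ratio. Only proper rotations are
   considered; the four sign choices are all explored (see below).
3. **Annealed robust point matching (RPM)**: soft-assign with an outlier
   slack row/column on the similarity
   f(s_n|v_m) = 1/(αβ) exp[−(d(s_n,v_m)/α + g(s_n,v_m)/β)],
   where d is the squared Euclidean distance (α is a temperature in
   voxel², the classic RPM convention) and g the chi-square distance of
   shape contexts. α decays (×0.93 per step, from 5× the larger of the
   target's mean squared nearest-neighbour distance and the subject's
   mean squared initial misalignment, down to 0.1), β grows by the same
   factor from a value equalizing the median magnitude of the two
   exponent terms — position dominates the coarse stage, local topology
   fine-tunes the cold stage. Each step re-fits a global affine to the
   soft targets; in the cold stage (α below 5% of its start) a PWA
   refit follows, letting the registration track smooth body bending.
   Hard correspondences come from the assignment solver on −log f.
4. **Mapping**: global affine then PWA fitted on current correspondences.
5. **Bipartite refinement**: per-pair similarity matrices from the atlas
   priors, f_spv = exp[−½ω⁻²‖(s_n−v_m)/σ_m‖²] and
   f_tsv = exp[−½ω⁻² g(s_n,v_m)²/γ_m²] (ω = 1; it rescales both families
   jointly). The assignment problem is solved on each separately and the
   consensus pairs (identical in both solutions) are kept; a consensus
   below 4 pairs (too few to fit the next mapping) falls back to the
   SPV-only assignment.
6. Steps 4–5 iterate until the correspondence set repeats (cycle
   detection) or 20 iterations. Every iterate is scored by the mean
   assignment cost −log(f_spv+f_tsv) of its induced full assignment and
   the best-scoring state wins — refinement can explore but never ends
   worse than the matching it started from. The final assignment is the
   Hungarian solution on F_spv + F_tsv; rectangular problems are padded,
   leaving surplus cells unidentified.

Because the PCA initialization is four-fold ambiguous, the whole
procedure runs from all four proper sign choices and keeps the result
with the lowest mean assignment cost. If even the best score is poor
(> 2.0), restarts shifted by ±1 and ±2 median nearest-neighbour
distances along the body axis are tried — this rescues the rare
axial-frame-shift lock-in where every cell captures a neighbour's
identity. All of this is deterministic given the inputs.

Ablation switches (`use_spv`, `use_tsv`) reduce the pipeline to
ASP-only matching (uniform σ, no consensus) or ASP+SPV, mirroring the
prior-contribution comparison in the evaluation.

## Metrics

Voxel accuracy is binary foreground agreement. Precision/recall/F1 are
instance-level with greedy one-to-one IoU matching at a threshold
(default 0.5). AJI is the aggregated Jaccard index. IIoU is the mean
per-ground-truth-cell IoU with best-overlap one-to-one pairing at any
positive overlap (unmatched cells contribute 0) — every cell counts
equally regardless of size. AP@t = TP/(TP+FP+FN); AP averages
t ∈ {0.50, …, 0.95}. Recognition AP additionally requires the matched
prediction to carry the ground-truth identity; a matched pair with the
wrong identity counts as one false positive.

## Synthetic data

* **Phantoms**: rejection-sampled cell centres with a minimum separation
  (default 9 voxels, 20 cells in 32×64×64), rendered as randomly
  oriented ellipsoids with axis ratios in [1, 2] (near-spherical
  nuclei), radii 3–5 voxels; the image is a sum of per-cell Gaussian
  blobs with amplitudes in [0.6, 1] (inhomogeneous brightness),
  Gaussian-blurred (σ = 1) with additive noise (σ = 0.03), min–max
  scaled. What this does not emulate: anisotropic PSFs, depth-dependent
  attenuation, autofluorescence, and truly touching cells with shared
  blurred interfaces — passing tests demonstrate the pipeline mechanics
  and learnability, not performance on real stacks.
* **Worm point sets**: K cells (default 100) sampled in a bent tube
  (length 400, radius 15 voxels, ≥ 6 voxels apart), emulating an
  elongated body plan at reduced cell count. Individuals apply a random
  affine (entries within ±0.1 of identity, translation ±10), a
  single-frequency sinusoidal bend of the body axis (amplitude 20
  voxels, random phase — the simplest deformation that separates PWA
  from affine), per-cell Gaussian jitter, and optional dropout.
  Real populations have structured, non-Gaussian variability and
  segmentation-induced spurious/merged cells beyond plain dropout.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen to
exercise every pipeline stage on a single CPU: 3-level network, five
32×64×64 training phantoms, 5 epochs × 200 cubes; K = 100 cells, S = 20
atlas samples, 10 evaluation worms per condition. Degenerate inputs are
defined: all-background masks give zero fields; an all-foreground mask
is an error; empty seed sets give all-background segmentations with a
warning; σ and γ are floored at 10⁻⁶ in the similarity denominators;
similarity values are floored at 10⁻³⁰⁰ before logs. Known limitations:
border cells inherit the inside-the-volume background convention; the
recognition score threshold for rescue restarts (2.0) is calibrated to
the synthetic regime; IIoU's pairing at any-overlap is one of several
defensible readings of a size-balanced instance IoU and is documented
as such.
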