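# Methods

## The pipeline

The package grades lumbar intervertebral disc (IVD) degeneration from
sagittal T2-weighted MRI in three stages: slice-wise semantic segmentation
(U-Net, 12 classes), 3D reconstruction of each disc into a point cloud in
millimetre coordinates, and 5-class Pfirrmann classification of the disc's
graph representation by a graph neural network.  Predictions for one disc
can be aggregated across samples by averaging probability vectors
(`training.aggregate_patient`), with argmax ties broken toward the more
severe grade — the clinically conservative choice.

## Synthetic phantom

The phantom stands in for a clinical cohort.  Geometry: six vertebral
bodies modelled as rounded cuboids (super-ellipsoid exponent 6) stacked
cranio-caudally along the image rows, and five discs as flattened
super-ellipsoids (exponent 2 cranio-caudally, 4 laterally) in the gaps.
Closed-form shapes were chosen deliberately so that voxel counts, extents,
and volumes have analytic oracles for testing.

A disc's Pfirrmann grade g ∈ {1..5} drives morphology through three
multiplicative factors, floored at 0.1:

| factor            | slope per grade step | emulates                      |
|-------------------|----------------------|-------------------------------|
| height_factor     | 1 − 0.12·(g−1)       | loss of disc height           |
| intensity_factor  | 1 − 0.18·(g−1)       | loss of T2 signal             |
| nucleus_contrast  | 1 − 0.22·(g−1)       | nucleus–annulus dedifferentiation |

Grade 1 is the identity reference.  Intensities: background 0.05,
vertebrae 0.45, annulus 0.25 + 0.15·intensity_factor, nucleus = annulus +
0.55·nucleus_contrast; all three observable disc properties therefore
decrease strictly with grade, which is the label-recovery signal the
pipeline is validated on.  Per-patient jitter (margins ±20%, lateral scale
±5%, column centre ±2%) prevents pixel-identical anatomy across patients.
Noise is additive Gaussian on the magnitude image (σ = noise_sd × max
intensity, default 0.03); a Rician option (`noise_model="rician"`) is more
faithful to MRI magnitude statistics but makes no practical difference at
this SNR.

Grades are drawn i.i.d. per disc from a configurable distribution whose
default (0.15, 0.27, 0.30, 0.20, 0.08) encodes the grade shares of a
typical ~60-year-old low-back-pain cohort (grades I–IV shares of 15/27/
30/20%, with the remainder assigned to grade V).  The full cohort is a
pure function of (spec, seed): volumes, masks, and grade tables are
bit-reproducible.

Simulated raters report round(truth + N(0, σ)) clipped to 1..5.  The
default σ = 0.45 was calibrated once so that two independent raters land
at a mean per-level Cohen's κ near 0.5, the moderate-agreement band
reported between spine surgeons; it also reproduces the qualitative
pattern that exact matches dominate and single-grade differences far
outnumber larger ones.

What the phantom does **not** model: Modic changes, herniation, scoliosis,
implants, partial-volume effects, coil-shading/bias fields, multi-scanner
intensity variation, or anatomically realistic texture.  Passing
label-recovery tests on phantoms therefore demonstrates that the pipeline
is implemented correctly and can extract a grade signal encoded in
geometry and intensity — not that it reaches any particular accuracy on
clinical data.

## Segmentation

Architecture: standard U-Net; two 3×3 convolutions + ReLU per level, 2×2
max-pooling, nearest-neighbour upsampling with skip concatenation, 1×1
head.  `base_features` filters at the top (default 32, doubling per
level), depth 4 by default.  Inputs are intensity slices normalized by the
volume maximum, plus two normalized coordinate planes (row, col): the
anatomy classes differ by spinal level, and translation-equivariant
convolutions otherwise have no access to absolute cranio-caudal position.

Training: Adam at learning rate 0.001, dice loss.  Three scheme choices
matter for from-scratch training and were each adopted after the simpler
variant failed:

* the macro soft-dice average includes the background class — with
  background excluded, background pixels receive no direct gradient and
  the optimizer parks their probability mass on an arbitrary foreground
  class and stalls;
* the first `ce_warmup_epochs` (default 5) use class-rebalanced
  cross-entropy (pixel weight ∝ count^−1/2 of its class in the batch)
  before switching to dice — pure dice from random initialization
  permanently starves some thin disc classes;
* gradients are clipped to global norm 5 and the learning rate drops by
  ×0.3 after two-thirds of the epochs — plain Adam on dice showed sudden
  divergence late in training.

Cross-validation is at patient level: `make_folds` shuffles patients,
cuts k near-equal test folds (default 10), and splits each fold's
remainder 85/15 into train/val.  No patient contributes slices to more
than one of train/val/test within a fold, and the k test sets partition
the cohort.

Metrics come from the voxel confusion matrix: per-class IoU, F1,
precision, recall; the Dice–Jaccard identity F1 = 2·IoU/(1+IoU) is
asserted in tests.  Classes with an empty union in both masks are flagged
and reported with metric 1.0; means are available with and without them,
and pixel-pooled (micro) metrics over class groups (all discs, all
vertebrae) are provided because slice-level tissue scores and per-level
macro scores answer different questions.

## Reconstruction

Masks become binary occupancy and masked-intensity scalar fields at the
native grid, spacing (slice, row, col) in millimetres; voxel centres sit
at index × spacing.  Surfaces are extracted by marching cubes at iso 0.5
on a zero-padded field (so border structures close), then refined:
HC/Humphrey smoothing (alpha 0.1, beta 0.5) — chosen over the λ/μ
(Taubin) filter because on thin plate-like discs at 3–4 mm slice spacing
Taubin shrank enclosed volume by 7–28% while HC stays under ~1.5% —
followed by edge splitting to a maximum edge length.  Refinement refuses
to return a mesh whose volume changed by more than 5% or that lost
closedness.

Samplers (all pure functions of input and seed):

* **voxel** — a uniform random subset of occupied voxel centres
  (default fraction 0.8, i.e. 80% of the voxels), intensities carried
  per voxel;
* **rejection** — uniform points inside the mesh by rejection from its
  bounding box; the inside test is vectorized ray-parity
  (Möller–Trumbore along a fixed non-axis-aligned direction), and an
  acceptance rate below 10⁻³ aborts with a diagnostic;
* **ellipsoid** — an axis-aligned ellipsoid fitted from the per-axis
  vertex extremes (centre = midpoint, semi-axes = half-extents), filled
  by a stratified jittered grid truncated to exactly n points (default
  1024); a PCA-aligned variant exists behind a flag.

For the mesh-based samplers, point intensities are the nearest occupied
voxel's value — an interpretation, flagged as such, since nothing in the
scheme definitions fixes it.

## Disc graphs

Coordinates are normalized isotropically about the centroid so the largest
absolute coordinate is 1; aspect ratios (hence the disc's oblateness, a
grade signal) are preserved.  Note one subtlety: because the scale is the
maximum |coordinate|, which is axis-dependent, the normalization is
exactly invariant to translation and scaling but only scale-covariant
under rotation.

Node features, fixed column order (versioned in the serialized header),
F = 48: intensity (1), centroid distance (1), six hypernode distances
(extreme node per axis/direction, ties to lowest index), 20 columns of
Laplacian-eigenvector positional encoding, 20 of random-walk encoding.
Edges: all ordered pairs within radius 0.1 in normalized space (symmetric,
no self-loops, optional degree cap); triangle faces can be converted to
edges and concatenated behind a flag (default off).

The Laplacian encoding takes, per connected component, the eigenvectors of
the symmetric normalized Laplacian for the k smallest nonzero eigenvalues,
unit-normalized, sign-fixed so the largest-magnitude entry is positive,
zero-padded when a component is too small.  Eigenvalues of this operator
lie in [0, 2].  On graphs with symmetric components or degenerate
eigenvalues the encoding is inherently defined only up to sign/basis — no
deterministic rule can canonicalize across graph automorphisms — which is
why permutation-invariance of the classifiers is tested on a fixed graph,
and why a random sign-flip augmentation hook exists for training.  The
random-walk encoding is the diagonal of (D⁻¹A)ᵗ for t = 1..20, with
isolated nodes given a self-loop so their walk is defined; rows of the
transition matrix sum to 1.

"20" for both encodings follows the standard reading of the construction
(k = 20 eigenvectors; 20 walk steps).

## Classifiers

* **baseline_gcn**: graph convolutions H ← Â H W with
  Â = D̃^−1/2 (A+I) D̃^−1/2 (self-loops keep edgeless graphs defined),
  ReLU and dropout between layers, global mean pooling, linear 5-class
  head.
* **dual_graph**: the GCN branch above, plus a point branch of two
  x-convolution stages — for each representative point (farthest-point
  sampling, started at the point nearest the centroid so the procedure is
  permutation-invariant), the k-nearest-neighbour patch's local offsets
  are lifted by a pointwise MLP, a learned K×K transform reweights the
  patch, and a dense map over the flattened patch emits the output
  feature (k default 16, two 4× downsamplings) — then the two pooled
  embeddings form a 2-token sequence passed through multi-head
  self-attention, mean-pooled, and classified.  Both branches currently
  receive the full feature set.

Hidden widths default (64, 128, 256), dropout 0.3, attention heads 4.
Both models are permutation-invariant at the graph level (mean pooling,
intrinsic FPS start); all parameters receive gradients (checked by probe).

## Classifier training

AdamW (decoupled weight decay; defaults lr 10⁻³, decay 10⁻²), up to 50
epochs, best-validation checkpoint retained, non-finite loss aborts to the
last good checkpoint.  Augmentation per presentation: a random 3D rotation
(axis uniform on the sphere, angle uniform within ±max_rotation_deg,
default 15°) plus Gaussian coordinate jitter (sd 0.01), after which the
graph — features, encodings, edges — is rebuilt from the moved points;
labels are untouched.

The objective is the weighted geometric mean of focal loss and
cross-entropy with per-class weights w_g ∝ 1/max(count_g, 1) normalized to
mean 1:

    L = exp(w·log(L_focal + ε) + (1−w)·log(L_CE + ε)),   ε = 10⁻⁸
    L_CE    = −w_t · log(p_t + ε)
    L_focal = −w_t · (1−p_t)^γ · log(p_t + ε)

Defaults γ = 2 and w = 0.5 (both exposed; nothing pins them externally).
The ε-flooring guarantees finiteness at p_t = 0, and the geometric
interpolation keeps L between its two components for any w ∈ [0, 1] — an
identity the tests assert.

## Rater statistics

Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from marginal
category frequencies, unweighted by default (a linear-weight variant
exists because the grades are ordinal); when both raters are constant and
identical the chance correction is undefined and the result is returned as
1 with a degeneracy flag.  Fleiss' κ uses the standard per-item agreement
formulation over an items × raters grid, complete-case with a warning.
Missing pairs are dropped pairwise for Cohen.  Both statistics are
invariant to category relabelling and converge to 0 for independent
uniform raters; implementations are cross-checked in the tests against
independent reference implementations.

## Validation scale and what it shows

The heavier checks run at sizes chosen for a single-CPU desk run: the
segmentation label-recovery check trains a base-16, depth-3 U-Net on a
20-patient cohort at 64×64×7 voxels (held-out mean foreground F1 ≥ 0.85;
measured 0.96 at the test seed), and the classifier check trains the
compact dual-graph model (hidden 32/64/64, k = 8) for 40 epochs on a
balanced 300-disc cohort at 96×96×9, with ~100–180-point voxel-sampled
clouds (held-out macro-F1 ≥ 0.7 with a permutation test against chance;
measured 0.75 at the test seed).  A full-size configuration (feature size
32, depth 4, 192×192×15, 1024-point clouds, 50 epochs) is the default in
the CLI config and runs the same code paths.

Known limitations: training the U-Net from a random start needs the
warm-up/scheduling described above, and held-out F1 on small cohorts
varies by a few points with the seed; the dual-graph model's accuracy on
phantoms says nothing quantitative about clinical MRI; full-run bitwise
reproducibility holds on a fixed platform but is not guaranteed across
BLAS implementations.
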