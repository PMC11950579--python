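# ivdpipe

Automated 3D reconstruction and Pfirrmann grading of lumbar intervertebral
discs from sagittal T2-weighted MRI — as a fully synthetic, end-to-end
testable pipeline.

Pfirrmann grading classifies disc degeneration into five ordinal levels
(I–V) from disc structure, T2 signal intensity, and disc height.  Human
grading shows only moderate inter-rater agreement (Cohen's κ typically
0.45–0.6), which motivates automated graders.  This package implements a
three-stage pipeline:

1. **Segmentation** — a multi-class U-Net labels each sagittal slice with
   12 classes (background, vertebral bodies L1–S1, discs L1/2–L5/S1),
   trained with patient-level cross-validation and dice loss.
2. **3D reconstruction** — per-disc binary masks become millimetre-space
   scalar fields (pixel spacing in-plane, slice spacing through-plane),
   surfaces via marching cubes with low-shrinkage smoothing and edge
   splitting, and point clouds via three samplers: native voxel centres
   (80% random subset), rejection sampling inside the mesh, and a
   regularized pattern inside the bounding ellipsoid.
3. **Graph classification** — each cloud is normalized to [−1,1] and turned
   into a graph (0.1-radius edges) with 48 node features: voxel intensity,
   distance to the disc centre (nucleus analogue), distances to six
   hypernodes (extreme point per axis), a 20-dimensional
   Laplacian-eigenvector positional encoding, and a 20-step random-walk
   encoding.  Two classifiers are provided: a baseline GCN and a
   dual-branch model (GCN + hierarchical x-convolutions over the point
   cloud, consolidated by multi-head attention), trained for up to 50
   epochs with AdamW, random rotation/jitter augmentation, and a weighted
   geometric mean of focal loss and cross-entropy against class imbalance.

Because clinical MRI cannot ship with code, the package includes a
**synthetic lumbar-spine phantom**: parametric volumes whose disc height,
signal intensity, and nucleus–annulus contrast decrease monotonically with
the sampled Pfirrmann grade, with ground-truth masks and grade tables.
Every stage is trainable and verifiable on phantoms alone.  Inter-rater
statistics (Cohen's κ, Fleiss' κ, agreement histograms) round out the
toolbox.

All neural components run on `ivdpipe.nn`, a compact numpy reverse-mode
autodiff engine included in the package, so the pipeline has no deep
learning framework dependency.

## Worked example

`examples/rater_agreement.py` simulates two surgeons grading a 120-patient
phantom cohort and computes the reliability report:

```
per-level Cohen's kappa (rater_A vs rater_B):
    L1/2: 0.425
    L2/3: 0.538
    L3/4: 0.516
    L4/5: 0.554
   L5/S1: 0.592
mean over levels: 0.525
Fleiss' kappa (three raters): 0.657
```

The per-level κ values sit in the moderate-agreement band observed between
human experts; the mean is the per-level average, the Fleiss value pools
three raters.  The other example scripts follow the same pattern:
`make_phantom.py` (cohort synthesis and grade→morphology coupling),
`segment_phantom.py` (U-Net training and the Dice–Jaccard identity),
`reconstruct_disc.py` (mesh volumes and the three samplers),
`grade_discs.py` (dual-graph classifier recovering grades above chance).

## Command line

The `ivdpipe` entry point chains the stages with config hashing and
per-stage seed derivation; rerunning an unchanged stage is a cached no-op:

```bash
ivdpipe all --config config.yaml --seed 7 --output runs/demo
ivdpipe kappa --config config.yaml --seed 7 --output runs/demo
```

Stage names: `phantom, segment, recon, graph, train, eval, kappa`.  All
pipeline constants (sampling fraction 0.8, graph radius 0.1, 20 encoding
dimensions/steps, 50 epochs, learning rate 0.001, U-Net feature size 32,
10 folds) are named defaults in the config.

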