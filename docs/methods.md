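# Methods

`gtvseg` implements a dual-modality workflow for delineating the gross
tumor volume (GTV) of lung lesions for stereotactic body radiotherapy
(SBRT) planning, when the FDG-PET was acquired on a diagnostic PET-CT
scanner in a different frame from the planning CT (pCT). The workflow has
three stages: rigid landmark registration of the diagnostic frame onto the
pCT, lesion-patch preprocessing, and voxel-wise segmentation with an
SE-Norm residual 3D U-Net trained under deep supervision.

## Coordinate model

Volumes are axis-aligned scalar grids with physical spacing and origin in
mm; voxel `(i, j, k)` sits at `origin + (i*sx, j*sy, k*sz)`. NIfTI files
with oblique direction cosines (beyond 1e-3) are rejected rather than
silently reinterpreted. Voxel indices are 0-based and crop windows are
half-open `[lo, hi)`. Rigid transforms are 4x4 homogeneous matrices mapping
moving-frame mm points into the fixed (pCT) frame; the rotation block must
be orthonormal with det = +1 within 1e-6.

## Rigid registration

The clinician-picked landmark pairs (8-10 per case in practice; >= 3 and
non-collinear required) are fit by closed-form orthogonal Procrustes
(Kabsch): centre both clouds, SVD the covariance, and flip the smallest
singular direction if needed so the solution is a proper rotation, never a
reflection. The fit minimizes the mean squared landmark mismatch; the RMS
residual is reported in mm. The PET is then pulled back onto the pCT grid:
each reference voxel's physical point is mapped through the inverse
transform and trilinearly interpolated (nearest-neighbour for masks so they
stay binary). Out-of-extent voxels receive a modality-neutral background:
-1000 HU for CT, 0 for PET and masks. Registration is only trusted inside
a 150 mm cube around the lesion (boundary inclusive); a smaller available
margin triggers a logged warning, not an error.

Transform files produced by external registration software carry no
orientation convention of their own, so the dialect is pinned here: JSON `{"matrix": 16 row-major floats,
"direction": "moving_to_fixed"}`, with a plain 4-line whitespace matrix
also accepted, and `moving_to_fixed` meaning diagnostic-frame ->
pCT-frame.

## Preprocessing

The chain is resample -> crop -> normalize, in that order, and is fully
deterministic:

* **Resampling** to isotropic 1 mm^3 (configurable) with trilinear
  interpolation; output shape is `ceil(extent / spacing)`, origin
  preserved, out-of-range samples clamp to the edge.
* **Cropping** a 144^3-voxel patch (configurable; 32^3 in desk-scale runs)
  whose centre is the truth-mask centroid during training and a
  user-supplied seed point (or the image centre) at inference — inference
  cannot assume a mask. Windows that overhang the image are padded with
  the modality background.
* **CT normalization**: clip to [-800, 800] HU, divide by 800, so -800,
  0, 800 map exactly to -1, 0, 1. Since the window is symmetric, the
  linear map and min-max rescaling coincide. A `normalized` flag on the
  volume guards accidental double application.
* **PET normalization**: per-patch Z-score with the population (divisor N)
  standard deviation; a patch with SD < 1e-8 maps to all zeros instead of
  propagating NaN.

## Network

A single-path 3D encoder-decoder consuming the CT and PET patches
concatenated as two channels (one channel for the single-modality
ablations). The convolutional block is conv3x3x3 -> ReLU -> SE Norm.

**SE Norm.** Channel-wise instance normalization (zero mean, unit variance
over spatial voxels, variance epsilon 1e-5) whose per-channel affine
parameters are *functions of the input*: a global average pool feeds a
bottleneck fully-connected layer (reduction ratio 2) with ReLU, from which
two parallel expansions produce a sigmoid-gated scale `gamma` and an
unbounded linear shift `beta`; the output is `gamma_c * norm(x_c) +
beta_c`. The micro-structure admits several variants; three
choices are pinned here: the squeeze pools the block
input (pre-normalization), `beta` is linear (unbounded), and the same
layer is used in encoder and decoder blocks. The bottleneck weights are
initialized non-negative (folded He) because the squeeze input is a pooled
post-ReLU mean and is therefore non-negative — this keeps every excitation
unit active at initialization, which zero-symmetric init does not
guarantee at small widths.

**Encoder.** `n_levels` = 4 down-samplings by 2x2x2 max pooling; each
resolution carries a residual block of two conv blocks with an identity
shortcut when channel counts match and a 1x1x1 projection otherwise.
Feature width starts at 24 and doubles per level: 24-48-96-192-384.

**Decoder.** Each stage up-samples with a 3x3x3 stride-2 transposed
convolution that exactly doubles every side (the output-size convention is
pinned to "exactly x2", implemented as the adjoint of a stride-2
convolution), halves the channels, concatenates the encoder skip, and
applies two conv blocks (mirroring the encoder depth). A final 1x1x1 convolution and channel softmax
yield the voxel-wise class probabilities.

**Deep supervision.** The three coarsest decoder stages carry auxiliary
heads: 1x1x1 convolution to the class channels, then trilinear
up-sampling to full patch resolution (separable x2 linear interpolation
with replicate edges, applied `k` times for factor `2^k`; its exact
adjoint is used in the backward pass). With fewer than four levels, heads
attach to all non-top decoder stages (`min(3, n_levels - 1)`).

**Implementation.** The network, its gradients, and Adam are written
directly on NumPy: convolutions as memory-bounded im2col + BLAS matmul
(float32), and every backward pass derived by hand and verified against
directional finite differences in the test suite. Weight init is He
fan-in for convolutions; shift-producing layers start at zero.

## Loss

Each head is scored with `L_i = L_Dice + L_Focal` on its softmax
probabilities; the total is `L = L_main + sum_i w_i L_aux_i`. The standard forms of both losses are used, all
configurable:

* soft Dice on the foreground channel, `1 - (2*sum(p*t)+s) / (sum(p) +
  sum(t) + s)`, smoothing `s = 1e-5`;
* focal loss `mean(-alpha_t (1-p_t)^gamma log p_t)` with `gamma = 2`,
  uniform `alpha = 0.5`, probabilities clamped at 1e-8;
* head weights `w = (0.5, 0.25, 0.125)` ordered fine-to-coarse, a
  conventional halving-with-depth decay; the main head carries weight 1.

Gradients with respect to the logits are analytic (Dice and focal
derivatives composed with the softmax Jacobian).

## Training protocol

* **Split**: cases sorted ascending by GTV voxel count, cut into 18
  near-equal strata, 3 cases per stratum drawn (seeded) into training, the
  remainder shuffled and split val:test at 18:14 — reproducing the
  54/18/14 protocol on an 86-case cohort.
* **Augmentation**: one random rotation about the axial axis, uniform in
  [0, 45] degrees (trilinear for images, nearest for masks), plus
  independent per-axis flips with p = 0.5, identical across CT/PET/mask,
  applied on the fly each epoch. 
* **Optimizer**: Adam, batch size 1, cosine annealing with warm restarts
  `lr = lr_min + (lr_max - lr_min)/2 (1 + cos(pi t/T))`, `lr_max = 1e-3`,
  `lr_min = 1e-6`, restart period T = 25 epochs (a no-restart single-cycle
  mode is available as a config option), 600 epochs at full scale.
* **Selection**: the checkpoint with the best mean validation DSC (DSC
  being the headline metric). Checkpoints are a weights file with a JSON
  architecture sidecar and round-trip exactly.

## Evaluation

With A the manual and B the automatic segmentation:

* `DSC = 2|A n B| / (|A| + |B|)`; both-empty pairs score 1.0, exactly-one-
  empty 0.0 (conventions chosen to keep cohort statistics well defined).
* `precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`; an empty prediction has
  precision 0.0 by convention.
* ASSD: surface voxels are foreground voxels with at least one
  face-adjacent (6-connectivity) background neighbour, with out-of-image
  treated as background; distances are Euclidean between voxel centres in
  mm; the symmetric average is taken over both surfaces. Empty masks make
  ASSD undefined — reported as missing, never 0. ASSD is computed on
  whatever grid the two masks share; the spacing is recorded in the
  report.
* Cohort summaries are mean ± SD (divisor n-1; SD 0 for n = 1). Methods
  are compared with a two-sided paired t-test; identical per-case values
  degenerate the test and report p = 1.0.

All four metrics are validated against exhaustive brute-force oracles
(explicit voxel loops, all-pairs surface distances) on random masks up to
16^3.

## Phantom generator

The phantom emulates the statistical structure the pipeline assumes, not
anatomy: a soft-tissue elliptic-cylinder body shell (~30 HU) around
lung-density background (-750 ± 40 HU), an ellipsoidal tumor (~40 HU) with
Gaussian texture, bright spherical fiducials (800 HU) on a jittered ring
in the body shell, and a PET with elevated tumor uptake (5:1 over
background) blurred by a 6 mm FWHM Gaussian PSF plus additive Gaussian
noise. The default grid is 80^3 voxels at 2 mm (160 mm extent, enough to
hold the 150 mm registration volume); cohort generation adapts the spacing
(clipped to [0.8, 2.0] mm) so the lesion spans ~6 voxels across its mean
radius, and draws tumor volumes log-uniform over 0.33-57.9 cm^3, the
clinical size range being emulated. An optional rigid misalignment places
the PET in a displaced frame; moving-frame volumes are generated by
evaluating the same analytic scene at rigidly transformed coordinates, so
the ground-truth transform and moving-frame truth mask are exact, with no
double interpolation.

What the phantom does *not* emulate: lesion texture and boundary
irregularity beyond an optional low-frequency radial wobble, respiratory
motion, attenuation/scatter physics, Poisson count statistics (PET noise
is Gaussian post-PSF), and anatomy-dependent uptake heterogeneity.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and trainable, not that clinical-grade accuracy transfers to
patient data.

## Desk-scale problem sizes

The full-scale protocol (86 patients, 144^3 patches, width 24, 600
epochs) is a GPU-scale computation; the package's self-contained runs use
reduced sizes chosen as the smallest that still exercise every stage
end-to-end: 12 phantoms, 32^3 patches, width 8 with 2 levels, 30 epochs
for the demo pipeline, and a 200-step single-phantom overfit sanity run.
At these sizes the demo reaches test DSC ~0.93 versus ~0.31 for an
untrained model, and the overfit run exceeds DSC 0.99 on its training
phantom. The full-scale architecture is still instantiated and run
forward at 144^3 to pin the shape contract.

## Known limitations

* Only axis-aligned volumes; no DICOM/RT-STRUCT I/O.
* Single-patch inference around a known seed point; no sliding-window
  whole-scan mode.
* Rotation augmentation interpolates on the patch grid with edge
  replication at corners.
* The NumPy engine is single-threaded BLAS-bound; it is meant for
  correctness and desk-scale studies, not full-scale training.
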