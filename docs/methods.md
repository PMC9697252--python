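# Methods

## Problem and scope

The package implements decision-level, hierarchical fusion for binary
classification of 3D volumes of interest (nodule vs non-nodule), the
false-positive-reduction stage of a lung-CT CAD pipeline, plus everything
needed to exercise it end to end on synthetic data: phantom generation with
simulated multi-reader annotations, consensus building, VOI extraction,
feature-image filtering, and level-wise evaluation.

## Phantom generator

Real archives supply bright, compact nodules and confusable distractors
annotated by several readers. The generator reproduces that statistical
skeleton, not CT physics:

* **Volume**: 96³ voxels at 0.6 mm isotropic spacing (a 30 mm cube spans 50
  native voxels, so VOI extraction genuinely resamples 50→56). Background is
  Gaussian noise, mean 0.10, sd 0.05.
* **Nodules**: additive anisotropic Gaussian blobs; axis-aligned extent
  5–12 mm with ±15% anisotropy; per-axis σ = extent/4, so the nominal extent
  corresponds to ≈ ±2σ of visible signal.
* **Distractors** (cycled): *tubes* (one axis elongated by a factor 4,
  radius 1.5 mm), *blobs* (nodule-shaped but dimmer), *speckle* (a local
  noise patch of radius 6 mm).
* **Separability dial**: `easy` draws nodule peaks in [0.90, 1.10] and
  distractor peaks in [0.20, 0.30] — nodule peak ≥ 3× distractor peak over
  the background noise, so a threshold on the raw central-voxel intensity
  separates the classes almost perfectly (the brute-force threshold oracle
  averages ≥ 0.99 over seeds). `hard` overlaps the ranges
  ([0.45, 0.70] vs [0.40, 0.65]); the same oracle drops to ≈ 0.74, forcing
  shape/texture discrimination.
* **Readers**: 4 simulated readers, isotropic Gaussian centre jitter
  sd 1.0 mm, per-reader miss probability 0.25; if all four miss, the miss
  draws are repeated, so every object keeps ≥ 1 annotation. The retained
  count is therefore Binomial(4, 0.75) conditioned on ≥ 1.
* **Placement**: rejection sampling with a 15 mm border margin and a 12 mm
  minimum pairwise separation, which keeps the 5 mm consensus threshold far
  below inter-object spacing.

What the phantoms do **not** model: Hounsfield calibration, reconstruction
kernels, anatomy (vessel trees, pleural attachment), or reader bias beyond
isotropic jitter. Passing tests on `easy` phantoms therefore demonstrates
that the pipeline's machinery (consensus, extraction, training protocol,
fusion) recovers a known signal — not clinical performance on real CT.

## Consensus and VOI extraction

Same-kind reader marks of one scan are merged by single-linkage clustering
of centre coordinates cut at a distance threshold (default 5 mm, above
plausible jitter and below object spacing). Each cluster yields the mean
centre, element-wise max extent, and the cluster size as approval count
(`min_approval` default 1). Nodule/non-nodule consensus pairs closer than
the same threshold are both discarded as reader disagreement.

A 30 mm cube around the consensus centre is cropped (window clamped inside
the scan near borders — shifting the centre rather than zero-padding, which
would leak label information through artificial black borders), resampled to
56³ by trilinear interpolation (`scipy.ndimage.map_coordinates`, order 1),
and min–max normalised to [0, 1]. A constant crop maps to all zeros; the
constant check uses a relative tolerance of 1e-9 because trilinear weights
do not sum to exactly one in floating point.

Slice selection: six plane indices per perspective via
`round(linspace(lo, hi, 6))` over the object span — the consensus extent
(converted to planes) centred in the cube for nodules, the full 56-plane
span for non-nodules, which carry no boundary annotation. One slice
(`n_slices=1`) takes the span midpoint. Degenerate spans repeat boundary
planes and are logged.

Splits are stratified with train size `floor(frac·N)` and per-class quotas
by largest remainder (604 balanced objects at 0.7 → exactly 422/182).

## Feature images

All filters operate per slice; boundaries are mirror-reflected (no edge
duplication) everywhere. Defaults (all exposed in `FilterSpec`): LoG σ=2;
Gabor σx=σy=2, centre frequency 0.1 cycles/pixel, real-part response
(magnitude optional); bilateral/trilateral 7×7 window, σ_S=2 px, σ_R=0.1 and
σ_L=0.1 on [0,1] intensities; difference-of-trilateral k=√2 (LoG kernel
radius ceil(3σ) captures >99% of mass). The trilateral's third kernel acts
on differences of discrete Laplacian responses computed once on the input
with the 4-neighbour stencil. The trilateral normaliser is the sum of the
full three-kernel weights, so a constant image is a fixed point. The
difference-of-trilateral operator is the difference of two filtered images
(scales k·σ_S and σ_S), not a kernel convolution. The vectorised
implementations are checked against nested-loop transliterations of the
definitions to 1e-10, and the limit reductions (trilateral→bilateral as
σ_L→∞, bilateral→Gaussian as σ_R→∞, Gabor→Gaussian as ω→0) to 1e-6.

## Classifiers and training protocol

The slice CNN and the fusion nets run on a compact seeded numpy core
(im2col convolution, 2×2 max-pool with floor cropping, dense layers, Adam,
softmax cross-entropy with probabilities clipped at 1e-12). A single
`numpy.random.Generator` drives initialisation (He/variance-scaled) and
batch shuffling, so a fixed seed reproduces training bit-for-bit — which is
what makes the modular-isolation contract (lower-level parameters
bit-identical after training higher levels) directly checkable via SHA-256
parameter digests.

Slice-CNN training defaults: Adam lr 1e-3, batch 32, up to 10 epochs with
early stopping (patience 3) on a 10% validation split; on the easy
benchmark, validation loss plateaus around epoch 8–10, and the cap keeps a
full three-seed fit within desk-scale runtimes. Fusion nets (MP/MV/top): one
hidden layer of 8 ReLU units, Adam lr 1e-2, up to 150 epochs, patience 15.
Slices inherit their VOI's label. MP/MV are trained on scores computed over
the same training objects used for the slice modules (no held-out stacking
split — a known overfitting risk at small n, acceptable here because the
fusion nets have ~100 parameters; an internal split can be emulated by
splitting upstream).

Scores are nodule-class softmax probabilities throughout; the decision rule
is argmax (0.5 on the nodule probability); ROC sweeps use the continuous
score with Mann–Whitney ½-credit for ties.

## Evaluation

Slice-level metrics treat individual slices (inherited labels) as units per
perspective; perspective and volume levels treat VOIs as units. Metrics with
empty denominators are NaN, never 0. fp/scan divides false-positive object
calls by the number of distinct evaluated scans; on phantoms a "scan" is one
generated volume, so the value is not comparable to archival per-scan rates
reported on clinical data.

## Benchmark sizes and observed behaviour

The standing benchmark is 604 objects in 151 scans (4 per scan), easy
separability, 70/30 split, three fit seeds — large enough for stable
statistics, small enough for a desk machine. The acceptance script and the
end-to-end tests recompute everything at this size. Observed on this
benchmark (and asserted by the tests): volume-level accuracy ≥ 0.95, mean
AUC non-decreasing slice → perspective → volume (within 0.02), shuffled-label
slice AUC within [0.4, 0.6], and multi-feature top-level fusion recovering
≥ 0.95 accuracy when one member is informative and the rest are chance.

## Known limitations

* Phantoms are deliberately simple; no claim transfers to clinical CT.
* The CNN is compact and CPU-oriented; no augmentation, dropout, or
  transfer learning.
* Multi-feature fusion at slice or perspective level (rather than volume
  level) is out of scope, as is joint end-to-end backpropagation — the
  modular protocol is the design.
* Gabor filtering uses a single orientation/scale rather than a bank.
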