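# Methods

This note documents the models, the parameter choices that matter, and the
limits of what the synthetic experiments can show.

## Phantom model

The anatomy is a single thigh modelled as concentric discs per axial
slice: fatty marrow inside cortical bone inside muscle inside a
subcutaneous-fat (SAT) ring, surrounded by background. Slice centers
follow a smooth sinusoidal in-plane wobble (default amplitude 2 mm per
axis) so the cylinder is not perfectly straight and patch content varies
along the stack. Real thighs — two per scan, with individual muscles,
fascia, vessels and partial-volume boundaries — are deliberately not
modelled: the phantom's job is to exercise every pipeline stage with an
exactly known ground truth, not to imitate clinical image statistics.

Default geometry: 64×64×48 voxels at 2×2×2 mm (the in-plane extent is the
smallest that holds a 50 mm thigh radius plus jitter; slice thickness
matches the 2 mm acquisition convention the volumetry assumes). Radii:
thigh 50 mm, SAT thickness 10 mm, cortical bone 8 mm, marrow 5 mm.

Signal synthesis follows the two-point Dixon decomposition. Each tissue
has a reference signal S and fat fraction ff:

| tissue   | S    | ff   |
|----------|------|------|
| muscle   | 1.00 | 0.05 |
| SAT      | 1.00 | 0.90 |
| cortical | 0.15 | 0.02 |
| marrow   | 0.90 | 0.80 |

water = S(1−ff), fat = S·ff, in-phase = water+fat, opposed-phase =
|water−fat|. The S/ff values are free parameters chosen once to make the
four classes separable in (water, fat) space the way they are on clinical
Dixon images (muscle water-dominant, SAT fat-dominant, cortical bone
dark, marrow bright on the fat image); they are not fitted to any scanner.

Degradations: a multiplicative bias field (random zero-mean quadratic in
normalized coordinates, scaled to ±`bias_amplitude`, default 0.10) models
coil-sensitivity-style intensity non-uniformity; Rician noise (default
σ = 0.05 of the mean foreground in-phase signal) models magnitude-MRI
noise. One bias field and one pair of Gaussian draws are generated per
phantom and applied identically to all four contrasts, so the channels
remain co-registered realizations of the same degradation and every
volume is bit-reproducible from its seed. Labels are exact (each voxel
belongs to exactly one class); there is no partial-volume mixing, which
is the main reason segmentation on phantoms is easier than on clinical
data — held-out Dice here bounds nothing about clinical performance.

## Cohort model

Each subject draws baseline volumes from normal distributions (defaults:
muscle 2600 ± 250 cm³, SAT 1195 ± 250 cm³, bone 300 ± 30 cm³ — SAT
matches the reported baseline mean; muscle and bone are realistic
two-thigh 22 cm-slab values for young women, since no absolute baselines
are reported for them). Post-intervention true values apply the percent
effects (+2.93 % muscle in IG, −0.62 % in CG, +2.8 % SAT over time in
both groups, bone unchanged), and every measurement is multiplied by a
log-normal error with σ = log(1 + CV), mean-centred so volumes stay
positive and unbiased; the default 1 % CV represents the repeatability of
automated volumetry. With zero noise the post/pre ratios are exact by
construction, which the tests use as an oracle.

`render_cohort_phantoms` maps cohort rows to images by choosing the class
radii as order statistics of the per-voxel radial distances: voxels are
ranked by distance to the slice axis and the bone/muscle/SAT cut-offs
placed exactly at the target voxel counts. This is radius scaling with
the threshold chosen on the discrete grid, and makes the voxel-counted
volume match the table to within half a voxel per class. Pre and post
scans of a subject share geometry (same jitter) and differ in noise.
Study-scale volumes (~4 L total) cannot fit the desk-scale grid, so
`CohortSpec.desk_scaled_to(base)` rescales baselines to the base
phantom's own class volumes while preserving percent effects and relative
SDs; the statistics are invariant to this overall scale.

## Patching

Cube 32, stride 16 (50 % overlap). Neither is reported for the original
system; 32³ is the largest cube that keeps CPU training practical and
divides cleanly across three resolution levels, and overlapping strides
smooth reconstruction seams. Boundary cubes are clamped inward rather
than zero-padded so every patch contains real data. Foreground is any
non-background voxel; the ≥ 5 % retention rule is inclusive at the
boundary. The 75/25 train/validation split is per patch (a seeded uniform
permutation, `floor(0.75 n)` to train); whether the original split was
per patch or per subject is unknowable from the description, and pooling
patches across phantoms before splitting is the more literal reading of
"75 % of the selected sub-volumes". Reconstruction averages class scores
over all covering cubes and takes the argmax, ties to the lowest class
index; voxels covered by no cube are background. At inference the
foreground filter is not applied (all tiles are predicted), since the
filter's purpose is training-set selection.

## Segmenter

Encoder–decoder with depth 3, base 8 filters, channel doubling, two
3×3×3 conv + ReLU layers per level, 2× max pooling and nearest-neighbour
upsampling. Skip connections carry encoder features to the decoder;
additive attention gates (1×1×1 projections of skip and upsampled gating
signal, ReLU, 1×1×1 to one channel, sigmoid) weight each skip voxel in
[0, 1]. "More connections between the layers" is realized as optional
dense decoder inputs: every coarser decoder output is 1×1×1-projected to
the base width and upsampled into each finer decoder level's concatenation.
Both mechanisms are toggleable so their ablation is testable; gates can
also be pinned open, which reproduces the ungated network exactly because
parameter initialization is seeded per named layer.

Training: soft-Dice + cross-entropy (the Dice term protects the 1 %-of-
voxels bone class), Adam at 1e-3, batch 2, 2 epochs, per-channel z-score
normalization estimated on the training patches. The epoch budget was
fixed from a convergence pilot: on this phantom family validation Dice
plateaus above 0.97 within ~160 optimizer steps, and the default
benchmark (30 phantoms → ~400 train patches) passes that point inside its
first epoch. The engine is a small reverse-mode autograd on NumPy;
convolutions run as per-offset channel GEMMs on contiguous shifted
copies, which keeps all BLAS operands contiguous. Everything is float32,
single-threaded-deterministic, and seeded; operator gradients are
verified against central differences and the convolution against an
independent `scipy.ndimage` oracle.

## Volumetry and statistics

Volumes are exact voxel counts × voxel volume (no partial-volume model,
matching the hard phantom labels); slabs are half-open slice intervals,
and the knee-anchored "110 slices" convention becomes an
(anchor, n_slices) parameter because phantoms have no knee. Dice of two
empty masks is defined as 1.0 (perfect agreement on absence).

The 2×2 mixed ANOVA uses the split-plot decomposition; with two time
points sphericity is automatic. Partial η² pairs each effect with the
error stratum it is tested against (GROUP → subjects-within-group; TIME
and TIME×GROUP → within-subject residual) — with n = 9 per group both
strata have 16 df, and this pairing makes η²ₚ = F/(F+16) reproduce the
published effect sizes from the published F values. Cohen's benchmarks
are applied as inclusive lower bounds. The KS normality test uses the
sample mean and SD as reference parameters, which makes the plain p-value
conservative (the Lilliefors caveat); a Lilliefors-corrected variant is
available behind a flag, and its rejection rate calibrates to the nominal
α in simulation while the plain variant stays below it. Tukey HSD
compares all four GROUP×TIME cell means with the within-subject error
mean square and its df — the comparison family is not stated in the
source description; the four-cell family is the choice that contains the
within-group pre-vs-post contrasts actually followed up. Degenerate
inputs (all-equal outcomes) return F = 0, p = 1 rather than 0/0.

One reported inconsistency is deliberately not reproduced: the SAT
interaction is published as F(1,16) = 0.06 with η²ₚ = 0.04, but
F/(F+16) ≈ 0.004; the pair is treated as a typo and excluded from the
effect-size consistency checks.

## Problem sizes and determinism

The held-out benchmark trains on 30 phantoms (≈ 540 patches → 405 train /
135 validation) and evaluates on 8 phantoms, all seeds derived from one
integer; this size makes the full run a ~10-minute single-core job while
keeping ≥ 400 optimizer steps per epoch and 8 independent test volumes.
Monte-Carlo calibrations use 200–1000 replicates with 3-SE acceptance
bands. All randomness flows through named, CRC-salted `SeedSequence`
streams, so phantoms, cohorts, splits, initialization and training are
bit-reproducible at a fixed thread count.

## Known limitations

- Phantoms have crisp single-tissue voxels, uniform per-class signal and
  simple geometry; Dice values obtained here are upper bounds of method
  health, not estimates of clinical accuracy.
- One thigh is modelled; reported volumes in pre/post studies may cover
  both, so absolute cohort baselines are scale conventions, not claims.
- No registration, bias-field correction or resampling: volumes that
  enter the statistics are assumed to come from the same grid convention
  at both time points.
- The repository-wide model/results object layout is used only for the
  statistics (`MixedAnova2x2` → `MixedAnovaResults`); the imaging side is
  a pipeline of functions over explicit volume types, which fits a
  multi-stage tool better than a single fitted-model abstraction.
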