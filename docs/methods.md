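# Methods

## Problem and model

Whole-slide images of excised AAA biopsies are segmented into five
classes — zone 1 (vascular wall), zone 2 (loose perivascular tissue,
PVT), thrombus, background, and an "ignore" label marking uncertain
zone borders and unannotated surroundings — and the resulting zone
masks are used to quantify immunopositive cells, DAB-stained area, and
elastin/collagen content per zone on serial sections.

### Tiling

Slides are cut into overlapping square tiles (default 384 px ≈ 175 µm
at 2.2 px/µm). The tile edge must be divisible by the network scaling
factor S = 2ⁿ; the divisibility check takes S from the configured
network depth rather than fixing n, since depth is itself a
hyperparameter. Default stride is half the tile (50% overlap). Edge
tiles are back-shifted into bounds rather than padded, so no synthetic
tissue is ever presented to the network. Tiles with more than 90%
ignore pixels are discarded; everything else is kept, with tiles at or
below 10% ignore additionally flagged "clean". Keeping the middle band
(10–90%) retains scarce-class pixels that would otherwise be lost.
Stitching averages per-pixel class probabilities over overlapping tiles
and argmaxes; uncovered pixels are an error, not a silent gap.

### Normalization and augmentation

Normalization uses per-channel mean/std over all pixels of the training
tiles. Using the training set only (not "the entire dataset" including
validation) avoids information leakage; this is a deliberate choice and
the statistics object records what it was computed over.

Augmentation draws, per sample, each transform from the menu
independently with probability 0.5 (the selection law is a design
choice; "one or several" transforms are applied on average).
Arithmetic transforms act on the input only, on a [0, 1] scale with
clipping: additive shift in [−0.07, 0.07], gain in [0.8, 1.2], pixel
dropout to black with fraction in [0.10, 0.50]. Geometric transforms
act on input and target identically with reflective edges: up-down and
left-right flips, rotation in [−90, 90]°, scaling in [0.8, 1.2], and
elastic deformation with a Simard-style displacement field (uniform
noise, Gaussian-smoothed with σ = 40, scaled by α ∈ [50, 200]).
Targets are warped with nearest-neighbor interpolation so the label set
can never grow. Geometric transforms are applied before arithmetic
ones; normalization happens at batch assembly, after augmentation.

### Network

A U-Net variant built from BSConv2 blocks — two repeats of
[reflection-padded 3×3 convolution (linear) → batch normalization →
trainable Swish] — with stride-2 convolutions for down-scaling, 2×2
stride-2 transposed convolutions for up-scaling, concatenating skip
connections (the classic U-Net merge; the alternative additive merge is
not used), and a 1×1 convolution + softmax head. Filters double per
level: base 32 at the surface means 256 at level 3 for the full-scale
depth-3 configuration. Weights are He-normal initialized; each Swish
has one learnable β initialized at 1.0 (recovering standard Swish).
Batch-norm momentum 0.9, ε = 1e-5, recorded in the config.

The stack is implemented directly in NumPy with explicit
forward/backward methods per layer (im2col convolutions; the
reflect-padding gradient is folded back through the exact `np.pad`
index map). Gradients are verified against central finite differences
in the tests. There is no pretraining; a weight-loading hook
(`UNet.load_state_dict`) accepts externally trained parameters.

### Training

Adam (defaults lr 1e-4, batch 8; the CPU-scale experiments in the tests
use lr 1e-3) minimizes the squared Jaccard distance on softmax
probabilities,

    L = 1 − Σ p·g / (Σ p² + Σ g² − Σ p·g),

with sums over classes and non-ignored pixels as one global ratio.
"Squared" is read as the squared-denominator soft-Jaccard variant; the
alternative reading (1 − J)² is not used. Ignore pixels are masked out
of numerator and denominator, so their gradient contribution is exactly
zero — the network is free to resolve the uncertain border regions.
Per epoch, loss, hard Jaccard and F1 (support-weighted over non-ignore
classes) are logged for training and validation sets; the checkpoint
with minimal validation loss is kept. Non-finite loss aborts with a
diagnostic. An optional early stop triggers once a target validation
Jaccard is reached.

### Evaluation conventions

Per-class metrics come from the pixel confusion matrix
(zero-denominator cells report 0). The identity J = F/(2−F) holds
exactly per class. Aggregates are macro (unweighted) or weighted
(support-weighted) means of precision/recall/F1; the **aggregate
Jaccard is obtained by converting the aggregate F1 through
J = F/(2−F)**, not by averaging per-class Jaccards. This convention is
adopted because it is the one under which the published aggregate rows
are self-consistent with their per-class rows; the plain mean is
available as `jaccard_convention="mean"`. Aggregates can exclude the
ignore class, and `correct_background` substitutes an estimated
background precision (recomputing background F1 from the original
recall, background Jaccard via the conversion, and all aggregate rows).
Zero-support classes are dropped from macro averages with a warning.
Reports render at 3 decimals; internal values keep full precision.
When the printed per-class rows (themselves rounded to 3 decimals) are
aggregated, the result can differ from a printed aggregate by one unit
in the last decimal; tests therefore compare reconstructed aggregates
at ±0.001.

### Zone masks and serial-section transfer

Per-class binary masks are cut directly from the argmax map; they are
mutually exclusive and, with the ignore pixels, partition the slide.
Mask area in mm² is pixels × (µm/px)² / 10⁶. Transfer to a serial
immunostained section is identity placement — no landmark registration
is attempted — but is gated by a quantitative QC score: the fraction of
detected tissue pixels (luminance below 0.9 of the estimated white
level, the 99th-percentile luminance) inside the union of the three
tissue masks. The default PASS gate of 0.8 is a configurable stand-in
for visual triage, not a calibrated reproduction of it.

### Stain model and quantification

Brightfield stains follow Beer–Lambert: OD = −log₁₀(I/I₀), stains mix
additively in OD space, and unmixing is a per-pixel solve against a
3×3 matrix of unit stain vectors. The H-DAB basis is the standard
Ruifrok–Johnston one. The OD transform is not clipped at zero, so
mix → unmix is exactly linear and invertible.

Positive cell detection (CD8/MPO semantics) works on the hematoxylin
concentration channel: a gray-scale opening with a disk of the
configured background radius (8 µm MPO, 10 µm CD8) estimates and
removes background; the signal is Gaussian-smoothed (σ 1.5 µm),
thresholded (0.2 OD — Gaussian smoothing dilates the suprathreshold
region, and a looser threshold was observed to bridge adjacent nuclei),
split by watershed seeded at distance-transform
peaks, and filtered to nucleus areas in [10, 400] µm². Compartments
are the nucleus, a 3 µm expansion ring (cytoplasm), and their union
(cell); a cell is positive when the mean DAB OD of the configured
compartment reaches the threshold (cytoplasm ≥ 0.2 for MPO, cell ≥ 0.1
for CD8). The smoothing σ, ring width, nucleus OD threshold and area
bounds are documented engineering choices — the reference interactive
tool does not publish its internals beyond the decision-relevant
parameters — and all live in `DetectionParams`.

Stained-area quantification (CD68 semantics) thresholds the DAB
concentration (default 0.2, configurable: the original threshold is
unpublished) and reports mm² and % per zone. Fiber classification
assigns each pixel with total OD ≥ 0.15 to elastin, collagen, or
neither by nearest reference-color direction (cosine similarity) in OD
space — an either/or decision by construction. Detections are
assigned to the zone whose mask contains their centroid; anything
outside the tissue masks, including ignore pixels, is reported under
background, matching how out-of-mask cells are accounted in practice.

## Synthetic study conditions

The generator emulates: (i) an annular biopsy cross-section — thrombus
core, zone 1 ring, zone 2 ring on an empty background, with seeded
angular wobble on the boundaries and an ignore band (default 4 px
half-width) along zone borders; a blob mode covers non-annular
morphology; (ii) Weigert-like rendering with per-zone background tint
and texture scale, adipocyte-like clear holes in zone 2, and fiber
pixels planted as exact counts (round(fraction × zone area)) from
ranked smooth random fields, so requested fractions are met to
sub-pixel accuracy before noise; (iii) H-DAB sections with
non-overlapping 8 µm nuclei placed on a jittered hexagonal lattice
(guaranteeing the spacing and making infeasible densities a detected
error), positives carrying DAB in the whole cell or the cytoplasm ring.
All color goes through the same forward OD model the analysis inverts,
plus additive Gaussian RGB noise (default σ = 0.02 of dynamic range).
Reference fiber colors are configuration, not measured ground truth;
no quantitative description of real Weigert color distributions was
available.

What the synthetic slides do **not** model: sectioning artifacts
(folds, tears, calcification damage), stain variability between
laboratories, chromatin texture inside nuclei, touching or overlapping
cells, and genuine inter-section deformation. Passing the recovery
tests therefore demonstrates that the pipeline inverts its own forward
model under noise and that the geometry/accounting is correct — not
that detection accuracy transfers to arbitrary clinical material.

## Problem sizes in the tests

Test-scale experiments use 256–768 px slides, 64 px tiles, and a
depth-2, base-8 U-Net. The training surrogate trains on two synthetic
slides and validates on a third, per seed, stopping once validation
Jaccard reaches 0.8 (reached within 13–19 epochs for all three tested
seeds). Counting recovery uses a 512 px section with 65 planted cells.
These sizes were chosen so the whole suite runs on a single CPU in a
few minutes while still exercising every stage end to end.

## Known limitations

- No landmark registration: displaced serial sections are detected
  (QC gate) but not corrected.
- The NumPy network is CPU-scale; full-slide, depth-3/base-32 training
  is out of its intended envelope.
- Aggregate-Jaccard and tile-filtering band conventions are inferred
  choices, documented above, not externally specified.
- The thrombus row of small areas is sensitive to area rounding when
  rates per mm² are derived from rounded areas.
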