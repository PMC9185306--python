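# Methods

This note documents the models implemented in endokit, the defaults and why
they were chosen, what the phantom generator does and does not emulate, and
the numerical conventions that matter for reproducing results.

## Enhancement

Grayscale conversion is the unweighted mean of R, G and B — deliberately
not the luminance weighting, since the chain is defined on the plain
channel average. The averaging filter replaces each pixel with the mean of
the `window² − 1` surrounding pixels (center excluded; 24 neighbors at the
default `window=5`); an inclusive 25-cell mode exists as a comparison flag.
The Laplacian defaults to the 4-connected stencil
`[[0,1,0],[1,−4,1],[0,1,0]]`, with the 8-connected variant selectable —
the continuous operator does not prescribe a discretization, and the
4-connected form is the conventional one. Borders are replicate-padded in
both filters. The enhanced image is the smoothed plane minus the Laplacian
response, kept in float64; clipping to [0, 255] happens only on PNG export,
with an optional `.npy` sidecar preserving exact values.

## Level-set segmentation

The model is a signed-pressure-force (SPF) region-based contour of the
Chan–Vese / SBGFRLS family. Region means use the arctan-smoothed Heaviside
with width ε = 1.5 px; an optional characteristic function can restrict
the domain of interest (default: the whole frame). The update is

    φ ← φ + dt · spf(I) · (λ·|∇φ| + ν),   spf = (I − (c1+c2)/2) / max|·|

with |∇φ| by central differences standing in for the Dirac-delta weighting
(the usual discrete simplification in this family), followed by a Gaussian
smoothing of φ with σ = 0.7 px in place of an explicit curvature term.
σ = 0.7 was set from the convergence behavior of the scheme: wider kernels
(σ ≈ 1) slow the interface enough that the area-change stop rule can fire
on a transient plateau before the contour reaches the object boundary,
while σ = 0.7 preserves noise robustness (it is applied every iteration)
without that artifact.

Defaults: λ = 1, ν = 0, dt = 1, SV = 0.1 %, max_iter = 500. The stop rule
is the relative area change |A_new − A_old| < (SV/100)·A_old; the
literal-shrinkage reading (stop only when the new area falls below SV% of
the old) would essentially never fire on a growing contour and is not
implemented. Initialization is φ = r₀ + 10⁻⁶ − distance-to-seed (a disc of
radius r₀ around the seed; the 10⁻⁶ counts pixel centers exactly on the
circle as inside, keeping the discrete disc area near πr₀²). After
convergence the mask is hole-filled (4-connectivity flood fill from the
border) and restricted to the connected component containing the seed, so
one seeded lesion is isolated per call. A flat image, a vanished contour,
or a contour that fills the frame each end evolution with an explanatory
stop reason rather than an error.

On disc phantoms (128×128, contrast 150 gray levels, radii 18–40 px) the
scheme reaches mean Dice ≈ 99.8 % noiseless and ≈ 99 % at noise σ = 10
across 10 seeds; the test suite asserts floors of 95 % and 90 %.

## Descriptors

**LBP.** Circular codes with P = 8 neighbors at radius R = 1, bilinearly
interpolated, `s(x) = 1 for x ≥ 0`, weight 2^p. Near-integer sampling
offsets are snapped to the grid so axial neighbors are exact; the codes
match scikit-image's `local_binary_pattern(method="default")` bit for bit
on interior pixels (asserted in tests). Codes from masked interior pixels
are histogrammed into equal-width bins over [0, 255] and normalized to
sum 1. The default bin count is 203, preserving the published descriptor
width; there is no standard 203-symbol LBP code space, so the equal-width
rebinning of the 256 codes is the package's interpretation, and an exact
256-bin mode is available.

**GLCM.** Intensities are uniformly quantized over the ROI's own range to
32 levels (configurable); co-occurrences are accumulated symmetrically for
the four offsets (0,1), (−1,1), (−1,0), (−1,−1) — axial steps at distance
1, diagonal steps at √2 — using only pixel pairs whose both endpoints are
masked. The classical 13 Haralick statistics (energy, contrast,
correlation, variance, inverse difference moment, sum average, sum
variance, sum entropy, entropy, difference variance, difference entropy,
and the two information measures of correlation) are computed per offset
with natural logarithms and 0·log 0 ≡ 0, then averaged over the four
offsets. Correlation-type features are defined as 0 when a marginal
variance vanishes; sum variance is centered on the sum average; the IMC2
exponent is clamped at 0 before the square root.

**FCH.** 16 fixed bin centers on a 4(R)×2(G)×2(B) lattice of channel
midpoints. The default fuzzy mode spreads each pixel over all centers with
membership ∝ 1/(d² + τ), τ = 1 guarding zero distance; the crisp mode
assigns each pixel to its nearest center and is the mode used by exact
counting tests. Red gets the finer partition because it dominates the
discriminative color variation in GI imagery.

**Fusion.** Concatenation in the order LBP, GLCM, FCH (203+13+16 = 232),
each value tagged with its block of origin. The hybrid vector prepends a
deep embedding: any callable with a declared output width can be plugged
in; the bundled fallback is a seeded random linear projection of a 16×16
block-averaged frame to 4096 values — deterministic per seed, used to
exercise the plumbing and the 4096/4328 shapes, and explicitly not a
learned feature extractor. Texture blocks are computed from the enhanced
grayscale plane, FCH from the original RGB pixels.

## Classifiers

The feed-forward network has one hidden layer of 30 ReLU units and a
softmax output — the published "30 hidden layers" is read as 30 hidden
*units* in a single layer, consistent with the 232-input/5-output topology
described alongside it; depth is nevertheless a config parameter. Training
is full-batch gradient descent on cross-entropy (with MSE between one-hot
targets and probabilities logged per epoch), inputs standardized by
train-split statistics, He initialization from the seed, L2 weight decay
1e−4, learning rate 0.5, up to 500 epochs. With a validation split the
validation loss is monitored every epoch, training stops after 25
non-improving epochs, and the best-epoch weights are restored. The "ANN"
and "FFNN" names in the CLI are presets of the same trainer; the genre
does not distinguish them architecturally.

The SVM is scikit-learn's `SVC` with a linear kernel, C = 1.0, one-vs-one
decision shape, behind a `StandardScaler` — kernel and C are unstated in
the genre's descriptions, so the simplest soft-margin default is used and
documented.

## Evaluation conventions

Stratified splitting shuffles each class with the seed, takes
round-half-up(n·0.2) for test, then round-half-up of 20 % of the remainder
for validation; 1000 per class gives exactly 640/160/200. Augmentation
yields 8 images per input: identity, horizontal and vertical flips,
rotations by 90°/180°/270°, a seeded translation of up to 10 % of the
frame, and a seeded zoom in [0.9, 1.1] — a fixed, seeded operation list
chosen for reproducibility. Only the training split may be augmented.

Confusion matrices are actual-by-predicted. Per-class rates are one-vs-rest
TP/TN/FP/FN percentages; macro values are unweighted class means; overall
accuracy is trace/total. A 0/0 rate (empty event set) is defined as 100 %,
which only arises on degenerate fixtures. ROC AUC is the standard
threshold-sweep area (trapezoid rule, equal to the Mann–Whitney pair
statistic, asserted in tests), reported ×100 — a printed "ratio of rates"
definition of AUC is not computable as a curve area and was not used.
`overall_accuracy` aggregates per-class accuracies by class-size weighting
and rounds to one decimal, matching how published per-class rows collapse
to a single figure. Mask scoring is pixelwise accuracy/precision/recall
plus Dice = 2TP/(2TP+FP+FN).

## Phantom generator

Phantoms are parametric cartoons of the five classes: per-class base
mucosa colors drawn from disjoint intervals, class-specific texture
(low-frequency waves for cecum, concentric rings for pylorus), a mild
radial vignette, and per-class lesions — a dye-tinted ellipse
(dyed-lifted-polyps), a bright ellipse with a specular spot (polyps), a
dark-red granular region (ulcerative colitis); the two normal classes have
no lesion and no mask. Lesion interiors differ from the surrounding mucosa
by at least ~60 gray levels before noise and never touch the border, so
segmentation contrast and class separability hold by construction. Default
frame size 128 px and pixel noise σ = 6 (moderate sensor noise relative to
the 60-level lesion contrast); per-image seeds derive from
`SeedSequence([master, class_index, item_index])` for reproducible
parallel generation.

What the phantoms do **not** emulate: real mucosal texture statistics,
specular highlight fields, motion blur, fluids/debris, the
picture-in-picture navigation box, or inter-patient variability. Passing
the end-to-end property (≥ 0.90 test accuracy at 100 phantoms per class)
therefore demonstrates that the pipeline's plumbing, descriptors and
training are correct and discriminative on controlled inputs — it is not
evidence about accuracy on clinical endoscopy images.

## Problem sizes

The test suite and the acceptance script use 16×16 images for oracle
equivalence checks, 128×128 discs (10 seeds × 2 noise levels) for the
segmentation floors, and 100 phantoms per class (500 images) for the
end-to-end study — sizes chosen so the full suite completes in well under
a minute of compute per stage on a single core while leaving the
statistical floors comfortable margins.

## Known limitations

- The 203-bin LBP histogram is a rebinning convention, not a canonical
  code space (see above).
- The SPF drive assumes one roughly homogeneous lesion brighter or darker
  than its surround; multi-lesion frames need one seeded call per lesion.
- The fallback deep extractor carries no learned semantics; hybrid-vector
  results with it only validate shapes and plumbing.
- Metrics assume single-label classification; no per-pixel multi-class
  segmentation scoring.
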