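# Methods

## Kernel derivation

The virtual hexagonal trellis places four virtual pixels h1..h4 at the
corners of the 3x3 neighborhood, each defined as the mean of one corner pixel
and the center fc (h1 pairs f1, h2 pairs f3, h3 pairs f7, h4 pairs f9, with
the layout f1 f2 f3 / f4 fc f6 / f7 f8 f9, row-major, origin top-left — the
unique layout under which the x-direction expansion maps onto the half-Sobel
x matrix). The directional differences are

* x: (f6 + h2 + h4) − (f4 + h1 + h3) = (2f6 + f3 + f9 − 2f4 − f1 − f7) / 2
* y: (h3 + h4) − (h1 + h2) = (f7 + f9 − f1 − f3) / 2

The central pixel cancels exactly in both; the symbolic stage uses
`fractions.Fraction` so this cancellation is exact rather than a
floating-point near-zero.

The y-expansion above does **not** equal the canonical half-Sobel y matrix
½[[1,2,1],[0,0,0],[−1,−2,−1]] (it lacks the center-column weight and has the
opposite sign convention). The package treats the half-Sobel matrices as
canonical for feature extraction — gradient texture statistics are invariant
to which of the two y-operators is used up to sign and scale — while the
symbolic module faithfully reproduces the raw expansion; both are exposed,
and the discrepancy is deliberate, not a bug.

The diagonal kernel comes from summing the two integer bracket matrices
(half prefactors dropped): [[0,2,2],[−2,0,2],[−2,−2,0]], whose nonzero
entries share the factor 2; the unit-scaled [[0,1,1],[−1,0,1],[−1,−1,0]] is
stored as `k45` with the factor recorded as metadata (`diagonal_factor=2`),
because the downstream statistics are scale-normalised and the absolute
scale of a gradient operator is immaterial. The 135° kernel is the column
mirror of `k45`: mirroring a 45° edge operator across the vertical axis
yields the orthogonal diagonal operator and preserves the zero-sum
invariant. Note that `k45` responds to intensity ramps along the c−r
diagonal and is blind to ramps along r+c (the x- and y-contributions cancel
there); tests assert both behaviours against direct dot products.

"Convolution" throughout the package is implemented as cross-correlation
(`scipy.ndimage.correlate`, reflective padding): kernel cell (r,c) aligns
with the neighborhood symbol at that position, which makes symbolic
evaluation and numeric filtering literally the same linear functional.

## COFE feature extraction

Images are converted to luminance with ITU-R 601 weights (0.299, 0.587,
0.114); the four response maps are pooled on a 4x4 grid of equal cells with
five statistics per cell — mean, mean absolute value, energy (mean square),
standard deviation, and the Pearson correlation between the cell's response
and its luminance values (zero-variance cells score 0, keeping all vectors
finite). Order is fixed: map-major (x, y, 45, 135), cells row-major, then
the five statistics. The length 4·16·5 = 320 is a hard contract: it depends
only on the configuration, never on image content. Grid and image side are
configurable (`VHTFeatureExtractor(grid=..., side=...)`), but 320 is the
default everywhere. The correlation-against-luminance statistic is this
package's concrete definition of "correlation between textures"; other
definitions (e.g. co-occurrence correlation) were deliberately not used.

Scaling covariance: multiplying intensities by a > 0 scales mean/abs-mean/SD
features by a, energy by a², and leaves correlations unchanged — asserted in
tests for a = 2 and a = 0.5.

## Synthetic smear generator

The generator emulates the features of stained single-cell smear crops that
drive gradient texture: a dark background (level 10–35) with out-of-focus
ghost blobs, a linear illumination gradient (±35% across the field), impulse
speckle (1% of pixels) and Gaussian sensor noise (sd 2.5); a pink,
low-contrast cytoplasm disk with harmonic boundary wobble; and a purple
nucleus with smooth chromatin mottling whose shape is the class signal —
lymphocyte: one round nucleus at 0.82 of the cell radius (area ratio ≈ 0.67,
always ≥ 0.6); monocyte: an ellipse with a deep circular indentation
(kidney); eosinophil: two elliptical lobes plus dense orange granule speckle
(5% of cytoplasm pixels, dilated to 2-px dots); neutrophil: 3–5 separate
lobes on a ring at 0.47 of the cell radius, sized so they never merge.
Cell radius defaults to 55–75 px on a 200-px field, matching a
high-magnification single-cell crop. All values were fixed once at design
time as a realistic caricature of Giemsa-type staining.

What the generator does **not** model: photorealistic stain variation,
red-cell/platelet clutter with instance structure, chromatin substructure,
focus blur gradients within the cell, or inter-laboratory colour shifts.
Passing tests therefore demonstrate that the pipeline's machinery works and
that its features respond to nucleus morphology; they do not certify
accuracy on real smears, which have far smaller between-class margins.

Determinism: every image is rendered from
`default_rng(SeedSequence([seed, class_index, image_index]))`, so a dataset
is byte-identical across runs and machines with the same numpy.

## Preprocessing and augmentation

Autocrop keeps the tight bounding box of pixels whose max channel ≥ 20
(manual workflows crop dark borders by eye; a fixed threshold makes the
pipeline unattended). Resizing is bilinear to 200x200. Balancing augments each class
to a target count by cycling rotation-right-90°, horizontal flip, vertical
flip and salt-and-pepper noise (density 0.02, half salt half pepper, exact
⌊d·H·W⌋ pixel count, per-copy seeds drawn from the balancing seed) over
uniformly sampled originals; originals are never removed.

## Deep surrogate and selection

The surrogate backend computes 8x8 block means and SDs of the luminance
plane and the four gradient maps (6250 statistics at 200x200) and projects
them through a fixed N(0, 1/√n) random matrix seeded by (seed, width) to
4096 dimensions. It is a deterministic, training-free feature source built
to exercise selection and fusion — it is not a CNN and makes no claim to
transfer; the `FeatureBackend` contract (`transform(images) -> n x dim`)
accepts any real embedding.

ACO selection: pheromone τ starts at 1, bounded to [0.01, 10]; heuristic η
is the per-feature Fisher ratio (between-class variance of class means over
mean within-class variance, ε = 1e-12, with exactly-constant features forced
to 0); ants sample k distinct indices ∝ τ^α η^β (α = β = 1, with a 1e-12
floor so zero-score features remain reachable); fitness is mean stratified
3-fold CV accuracy of a standardised linear SVM on the subset (fitness
values are cached per subset); evaporation ρ = 0.2 with an
iteration-best deposit equal to its fitness; 20 ants × 30 iterations by
default. The subset size k is exact, not emergent, because fusion
experiments are defined by exact counts. Elitist bookkeeping makes the
best-fitness history non-decreasing by construction.

## Classification and evaluation

All classifier variants standardise features with training statistics only.
SVM variants follow the familiar toolbox naming: linear; polynomial degree
2/3 with coef0 = 1; RBF with kernel scale √d/4, √d, 4√d for d features
(gamma = 1/s²), box constraint 1, one-vs-one multiclass with OvR decision
scores for ROC. KNN: fine k=1, coarse k=100 (clipped to the training size),
cosine k=10. The train/test protocol is a stratified, seeded 75/25 split.

The evaluation report contains the 4x4 confusion matrix (rows = truth);
per-class one-vs-rest sensitivity, specificity, PPV, NPV, accuracy, F- and
G-measure with every 0/0 defined as 0; unweighted macro averages over the
classes present; overall accuracy = trace/total with error = 1 − overall
(the two bookkeeping identities "per-class TP+FP+FN+TN = total" and
"accuracy + error = 1" are asserted in tests); and trapezoidal one-vs-rest
AUCs from decision scores. A class absent from both truth and prediction is
reported as undefined (None) and excluded from macros.

When a fusion experiment uses fewer than 320 VHT features, the VHT side is
truncated to its first k features in layout order — the gradient-map and
grid-cell ordering is fixed, so truncation is deterministic and
reproducible; no VHT-side selection is performed.

## Problem sizes and numerical choices

The bundled end-to-end benchmark uses 150 synthetic images per class
(600 total), the 4096-d surrogate, ACO defaults with k = 100, and a cubic
SVM on the fused 200-vector — chosen as the smallest configuration at which
all stages (selection in particular) operate in their intended regime.
Determinism checks use a reduced configuration (15/class, 256-d surrogate,
4 ants × 3 iterations) since they only compare artifacts between identical
runs. Ties in ACO subset fitness resolve to the first subset encountered;
JSON artifacts are written with sorted keys; stage timings go to a separate
log file so reports stay byte-reproducible.

## Known limitations

* The surrogate backend's features are random projections of low-order
  patch statistics; a trained CNN would behave differently under selection.
* Synthetic classes are far more separable than real ALL-IDB2-style data;
  reported synthetic accuracies are upper bounds on machinery health, not
  biological performance claims.
* The 135° kernel is a design choice (column mirror of the 45° kernel); it
  is defined by symmetry rather than derived from the trellis.
* The feature count is fixed at 320 by construction; configurations quoted
  elsewhere as "320–350 depending on the image" are not reproducible with a
  fixed-size pooling design.
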