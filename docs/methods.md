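# Methods

This note records the models, parameter choices and numerical conventions
behind `brushcyto`, including the places where the design was genuinely
open and a choice had to be made.

## The measurement model

The unit of analysis is the *cell cluster*: a connected group of epithelial
cells on a 40x brush-cytology slide. The working assumptions are that
(i) clusters are darker than the slide background, (ii) nuclei are darker
than cytoplasm after equalization, and (iii) malignancy expresses itself in
nuclear geometry (larger minor axis, lower solidity, i.e. more irregular
boundaries) and in intranuclear/perinuclear texture (chromatin
heterogeneity, entropy around nuclear membranes). The feature vector is
deliberately hand-crafted and named, so every coefficient of a downstream
model maps back to an interpretable morphological quantity.

## Preprocessing

* **Background threshold.** The bright slide mode is estimated as the
  pixels above the Otsu split of the crop; the foreground/background
  threshold is placed at that mode's mean minus three standard deviations
  (foreground = strictly below). Placing the cut at the lower edge of the
  background mode rather than at its mean matters under realistic pixel
  noise: half of the background pixels sit below their own mean and would
  otherwise leak into the foreground.
* **Area floor.** Objects under 100 µm² (stain debris, single cells, pen
  marks) are removed; at the default calibration of 0.25 µm/px that is
  1600 px. The comparison is strict (`area < floor` removed).
* **Equalization.** Histogram equalization uses a 256-bin CDF computed
  over foreground pixels only — background would otherwise dominate the
  histogram — and maps all pixels through the same monotone curve, so
  intensity rank order is preserved. Order of operations is fixed as
  background removal → small-object removal → equalization.
* **Illumination normalization.** Texture extraction operates on
  `image − local mean` with a 15×15 window and reflect padding (reflect
  avoids edge darkening; the window is clamped to the crop for unusually
  small crops).

## Cluster detection

Slide-scale images are tiled into non-overlapping 1000×1000 px patches
(row-major, right/bottom remainders dropped; all coordinates 0-based,
half-open). A patch is discarded when more than 40% of its pixels lie at
or above the background threshold; the same threshold then defines the
foreground whose connected components (≥ 100 µm²) become cluster crops.
Using one threshold for both rules keeps the two definitions consistent.
Clusters spanning patch boundaries are not stitched — a known recall
limitation of grid tiling.

## Nuclear segmentation

Nuclei are binarized by Otsu's threshold over the foreground intensities
(dark side = nuclei), holes filled, specks under 6 µm² dropped. Touching
nuclei are separated by watershed on the negative Euclidean distance map.
Markers are the h-maxima of the distance map with depth 2 px — the
standard remedy for distance-transform chatter — after a Gaussian
smoothing of the distance map (σ = 1 px) that removes spurious ridge
maxima caused by boundary irregularity. A watershed line (≤ 2 px) is kept
between labels. Nuclei touching the crop border are retained; excluding
them would bias shape statistics in small crops. No special handling
exists for heavily overlapping atypical nuclei; counts there are
approximate.

## Texture bank (495 features)

* **Haralick (13 maps).** For every pixel, a symmetric co-occurrence
  matrix is accumulated over the 5×5 window from the four standard
  distance-1 offsets (0°, 45°, 90°, 135°; direction-averaged for rotation
  robustness), on a 64-level quantization spanning the min–max of the
  foreground intensities. The 13 classical statistics are energy,
  contrast, correlation, variance, inverse difference moment, sum
  average, sum variance, sum entropy, entropy, difference variance,
  difference entropy, and the two information measures of correlation.
  Sum variance is centred on the sum average (the convention adopted by
  most modern implementations). Logarithms are natural; degenerate
  windows report correlation 0 and information measure 1 as 0. For
  symmetric matrices HXY1 = HX + HY and HXY2 = 2·HX, which the kernel
  uses directly; the test-suite oracle computes the general definitions
  instead, so the identity is verified rather than assumed.
* **CoLlAGe (13 maps).** Per-pixel gradients (central differences) are
  stacked over the 5×5 window; the dominant orientation is the leading
  right singular direction of that stack, computed via the 2×2 windowed
  structure tensor (algebraically identical, verified against a
  per-window SVD oracle to 1e-8 rad mod π). Orientations in [0, π) are
  quantized into 64 bins — matching the Haralick quantization — and the
  same 13 co-occurrence statistics are computed on the binned orientation
  image. Zero-gradient windows map to bin 0.
* **Gabor (48 maps).** A complex Gabor bank over 6 frequencies in a
  geometric series 0.05–0.4 cycles/px × 8 orientations 0–7π/8. The 48
  filter count is the binding contract; the exact grid is a design
  choice. Kernels are made DC-free by subtracting the real part's mean so
  flat regions respond zero; the response is the complex magnitude,
  convolved via FFT.
* **Law's (25 maps).** All ordered outer products of the classical
  five-tap vectors L5 = [1,4,6,4,1], E5 = [−1,−2,0,2,1],
  S5 = [−1,0,2,0,−1], W5 = [−1,2,0,−2,1], R5 = [1,−4,6,−4,1], applied as
  sliding dot products (no kernel flip) with reflect padding.
* **Summarization.** Each map is reduced over the cluster foreground
  (not the bounding box) with mean, median, population standard
  deviation, population skewness and plain kurtosis (Gaussian = 3, not
  excess). Degenerate zero-variance samples report skewness = kurtosis
  = 0 with a warning. At least 4 foreground pixels are required.
  Feature names follow `family.descriptor.statistic` and are bijective.

## Shape bank (41 features)

Eight descriptors per nucleus: area, perimeter (Crofton estimator),
major/minor axis lengths of the moment-equivalent ellipse, eccentricity,
solidity, circularity 4πA/P², equivalent diameter; lengths in µm, areas in
µm². The 8 × 5 aggregation uses the same five statistics, and the N:C
ratio (total nuclear area / non-nuclear foreground area) completes the 41.
The exact membership of the 40 aggregate features is a documented reading:
8 descriptors × 5 statistics, with the descriptor set chosen to contain
every shape feature the method's results single out (perimeter, solidity,
minor axis length) plus their standard companions.

**Solidity** is pixel area divided by the area of the convex-hull
*polygon* of pixel centres. The common alternative — re-rasterizing the
hull and counting pixels — biases solidity down severely for small
regions (a rasterized disc of radius 12 px scores 0.948); the polygon
form is nearly unbiased and may exceed 1 by a raster epsilon on convex
shapes, which callers should treat as exact 1.

## Selection and classification

* **Univariate ranking** uses the two-sided Wilcoxon rank-sum (exact for
  small samples via scipy) or two-sided t-test; features are ordered by
  ascending p, ties broken by larger effect size (rank-biserial deviation
  or standardized mean difference) then name. Constant features get p = 1
  with a warning. The fold-level selection takes the top 5 among features
  passing α = 0.05 (falling back to the global top 5 when fewer pass).
  No multiple-testing correction is applied beyond the α filter and the
  frequency-of-selection criterion.
* **mRMR** scores relevance as the absolute point-biserial correlation
  with the label and redundancy as mean pairwise |Pearson r|; the greedy
  forward step maximizes the set objective (mean relevance − mean
  redundancy) of the augmented selection, and candidates with |r| > 0.7
  to any selected feature are pruned outright.
* **Multi-expert balancing** follows the b/m scheme exactly; when
  (m − b) > b the second expert's minority draw is necessarily with
  replacement (sampling (m − b) from b without replacement is impossible
  in that regime). Balanced classes collapse to a single expert on all
  data. Training index sets are retained for audit.
* **Base learners**: LDA, QDA (tiny ridge 1e-6 for numerical safety), and
  a bagged ensemble of 100 entropy-split decision trees (the tree count
  is a design choice; only the ensemble family is prescribed).
* **Cross-validation** is stratified at patient level — every cluster of
  a patient stays in one fold, since cluster-level splitting would leak —
  with 3 folds re-randomized per iteration (defaults: 100 iterations;
  the shipped experiments use 20 to keep runtimes desk-scale). Selection
  is refit inside each training fold. Metrics are computed on the pooled
  held-out predictions of each iteration and reported as mean ± sd.
* **ROC** uses a threshold grid of the sorted unique probabilities plus
  endpoints, `p ≥ t` counting as positive, trapezoidal AUC with ties
  ordered by (FPR, TPR). Patient-level probabilities aggregate cluster
  probabilities by mean (median/max configurable).

## Synthetic data

The generator emulates what the pipeline assumes, not what slides look
like: nuclei are radially perturbed ellipses (sinusoidal perturbation,
4–8 lobes; the amplitude is adapted by bounded rejection until the
rendered solidity hits the target ±0.015), chromatin is a smoothed
Gaussian noise field whose sd is `chromatin_heterogeneity` × 12 gray
levels, cytoplasm is a dilated blob around the nuclear union, and
Gaussian pixel noise (sd 2) covers everything. Default calibration is
0.25 µm/px, typical for 40x scans. The benign preset uses minor axis
5.0 ± 0.5 µm, solidity 0.97, heterogeneity 0.5; the malignant preset
6.5 ± 0.5 µm (three preset-sd larger), solidity 0.90, heterogeneity 2.0,
and more frequent nucleus contact — the documented directions of effect,
since no numeric size distributions are published for this material.
Cohorts assign 5 single-label clusters per synthetic patient.

Not emulated: photorealistic staining, color variation, focal-plane
blur, overlapping-cell occlusion of cytoplasm. Passing label-recovery
tests therefore demonstrates that the pipeline recovers planted
morphological signal through the full extraction-selection-classification
chain; it does not certify performance on clinical material.

## Problem sizes and determinism

The label-recovery experiment uses 30 + 30 synthetic patients × 5
clusters (300 feature vectors per arm) and 20 CV iterations — sizes
chosen to keep the full recomputation around ten minutes on one CPU while
leaving the Monte-Carlo error on the AUC well under the margins being
asserted. Every random quantity (rendering, placement, resampling, fold
assignment) derives from an explicit integer seed; repeated runs are
bit-identical.

## Known limitations

* Watershed under-/over-segments heavily overlapped or atypical nuclei.
* Grid tiling never stitches clusters across patch boundaries.
* Probabilities are not calibrated; the 0.3 operating threshold is an
  inherited convention, not a fitted quantity.
* The mRMR relevance functional and the exact Gabor grid are documented
  design choices standing in for unpublished originals; the family
  structure and counts (48 Gabor, 13 + 13 co-occurrence, 25 Law's) are
  the binding contract.
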