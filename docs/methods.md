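# Methods

`crownmap` implements an object-based machine-vision chain for identifying
and mapping individual trees from UAV RGB orthomosaics and a photogrammetric
digital surface model (DSM). This note records the models, the parameters
that matter, the synthetic benchmark that stands in for field imagery, and
the numerical choices made where the design was genuinely open.

## Terrain and layer stack

The slope model is Horn's 3x3 weighted finite-difference slope in degrees —
the default of mainstream GIS slope tools — computed on the DSM with
clamp-to-edge padding so the raster keeps its shape. Cells whose
neighbourhood touches nodata propagate NaN. Slope highlights the steep rims
of tree crowns and near-zero understory, which is why it enters the
segmentation stack at high weight.

Segmentation consumes a five-band stack [R, G, B, DSM, slope] on the
orthomosaic grid. DSM-resolution layers (typically 10 cm against a 5 cm
ortho) are resampled bilinearly with pixel-centre registration, then DSM and
slope are min-max scaled to the 0–255 byte range so the per-layer weights
act on commensurate units.

## Multiresolution region merging

Segmentation is bottom-up region merging in the Baatz–Schäpe tradition.
Every valid pixel starts as a segment; fusing adjacent segments a, b is
admissible while the heterogeneity increase stays below `scale**2`:

    f = (1 - w_shape) * dh_colour + w_shape * dh_shape
    dh_colour = sum_c w_c (n_m sd_c,m - n_a sd_c,a - n_b sd_c,b)
    dh_shape  = w_cmpct * dh_compactness + (1 - w_cmpct) * dh_smoothness

with population SDs (defined for single-pixel segments), compactness
`perimeter / sqrt(n)` and smoothness `perimeter / bbox-perimeter`, each
size-scaled by n in the increase. Adjacency and connected components are
4-connected to prevent diagonal leakage across crown boundaries.

Merging proceeds in **synchronous mutual-best-fitting passes**: each pass
computes all admissible pair costs vectorised over the current adjacency
graph, every segment points at its cheapest neighbour (ties broken by
seeded random priorities), and exactly the pairs that point at each other
merge. This is the canonical local mutual-best-fitting criterion realised
in whole-graph passes rather than a sequential pixel scan; the pass
structure is what lets a 512x512 scene segment from 262k single-pixel
seeds in seconds on one core, and it keeps runs bit-reproducible for a
fixed seed. Segment statistics (count, per-band sum/sum-of-squares,
perimeter via shared-edge bookkeeping, bounding box) are maintained
incrementally and verified against batch recomputation in the tests.

Tuned defaults, found by trial and error on the synthetic benchmark in the
spirit of the usual interactive calibration of such segmenters:
`scale = 220`, `w_shape = 0.3`, `w_cmpct = 0.8`, layer weights
R=G=B=1, DSM=0.3, slope=4. Slope dominates because crown rims are the most
reliable boundary evidence; the raw DSM is down-weighted because a crown's
own cone spans a large elevation range and would otherwise penalise
within-crown merges.

## Segmentation scoring

Segments are scored against reference crowns by overlap fraction
(intersection area / reference area; intersection-over-union available):
Matched (> 80 %), Nearly matched (60–80 %], Split (20–60 %], Merged
(two or more crowns each overlapped > 20 %; subdivided one-class vs
multi-class), Fragmented (everything touched at most 20 %). Boundary
closure at exactly 60 % and 20 % is downward. Segments with zero crown
intersection and centroid outside all crowns are non-forest background and
are excluded from the tabulation. `crown_recovery` inverts the view: a
crown counts as recovered when some segment captures it as Matched or
Nearly matched.

## Texture features

The grey image is the 8-bit luminance (0.299 R + 0.587 G + 0.114 B),
rescaled to 5-bit (32 levels) by `floor(v / 8)` before co-occurrence
counting. The grey-level co-occurrence matrix (GLCM) accumulates
distance-1 pairs in the four directions 0/45/90/135 degrees symmetrically
into a single normalized matrix — the common rotation-robust convention;
offsets are configurable. Five statistics summarise a matrix P:
ASM `sum P^2`, contrast `sum P (i-j)^2`, dissimilarity `sum P |i-j|`,
entropy `-sum P ln P` (natural log, `0 ln 0 := 0`), homogeneity
`sum P / (1 + (i-j)^2)`. Texture entropy is conventionally non-negative,
so the implementation carries the minus sign.

Per-pixel texture maps evaluate these statistics over a centred k x k
window, excluding the (k-1)/2 margin. The implementation aggregates exact
integer window sums per grey-level pair via summed-area tables, making the
cost O(pairs x pixels) independent of k; it is verified to 1e-12 against a
per-window brute-force oracle.

An object's feature vector is 16 numbers: mean and population SD of each
RGB band over the object mask, plus mean and SD of the five texture maps
over masked pixels with valid windows. Objects lying entirely inside the
margin at a given kernel are dropped from that kernel's feature table with
a warning. The kernel-size sweep recomputes features at sizes
{3, 11, 19, 27, 35, 43, 51, 59}, runs the SVM grid search per size, and
selects the size with the highest mean validation accuracy (ties to the
smallest size).

## Classification protocol

Items are randomly divided into four equal-as-possible subsets; each of the
four rotations trains on two, validates on one (hyper-parameter selection)
and tests on one, and every subset is the test set exactly once. All test
predictions are pooled into a single confusion matrix; overall accuracy is
trace/total, Cohen's kappa is `(p_o - p_e) / (1 - p_e)` with chance
agreement from the marginals, per-class F1 is the harmonic mean of
precision and recall (0 where undefined), macro F1 their unweighted mean.

The SVM is a radial-basis-function machine grid-searched over gamma
{1e-1..1e-5} and cost {1..1e5} in decade steps (30 candidates per
rotation) on features z-scored with training-fold statistics — RBF
machines are scale-sensitive, so standardization is applied even though it
is an implementation choice.

The CNN is a small convolutional network written on numpy with explicit
forward/backward passes: three conv(3x3)/ReLU/max-pool stages
(16-32-32 channels), global average pooling and a linear head, trained
from scratch with Adam (lr 1e-3, batch 32) on softmax cross-entropy.
Training images are augmented eight-fold with the dihedral transforms
strictly after the split; inputs follow the random-resized-crop (train,
area 0.08–1.0, aspect 3/4–4/3) and resize-shorter-side-then-centre-crop
(eval) protocol, one patch per image. The full-size protocol constants are
224/256; the benchmark runs the identical protocol at 64/72 because the
synthetic crowns are 50–90 px across and the smaller patch keeps the
from-scratch network trainable in minutes on one core. Pretrained large
backbones are deliberately out of scope: they would need a weight
download, and the explicit backward pass is what powers the attention
maps. Runs are deterministic for fixed seeds on one device.

## Attention maps

Grad-CAM weighs a conv stage's feature maps by the spatial mean of the
target-class logit's gradients, rectifies the weighted sum and upsamples it
bilinearly to the patch. Guided backpropagation computes the input
gradient with every rectifier's backward pass zeroing both negative
upstream gradients and inactive positions. Guided Grad-CAM is their
elementwise product (channel gradients folded by summed absolute value);
its support is contained in the Grad-CAM support by construction. The
default layer is the last conv stage; any named stage works. Displayed
overlays are max-absolute normalized per patch — a rendering choice with no
analysis effect. All gradient paths are finite-difference-checked to 1e-4
relative.

## Synthetic forest benchmark

No field imagery ships with the package, so every stage is exercised on a
seeded generator that emulates the structure such a study scene has:

* 512x512 px orthomosaic at 5 cm GSD (≈ 26 m square), DSM at 10 cm;
* 40 crowns over the 7-class scheme (four tree types, two pine species
  groups, non-forest), radii 26–42 px (1.3–2.1 m), placed large-first by
  dart throwing with a centre-distance overlap allowance of 0.15;
* each crown is a star-convex jittered disk with a class-specific base
  colour, plus **per-crown** band-limited Gaussian noise whose spatial
  frequency is class-specific (0.06–0.29 cycles/px) — the fine-scale
  foliage-contrast cue; trees are individuals, so adjacent same-class
  crowns do not share texture phase;
* mild 8 % apex-to-rim shading and a 3 px rim-shadow band emulating the
  dark inter-crown gaps of a nadir view;
* a cone-shaped DSM bump per crown (apex at centre, height 8–22 m) on a
  gently tilted ground plane; overlapping cones combine by maximum;
* understory/bare-ground background with coarse low-contrast texture.

Reference outlines are the **visible** crown extents under canopy layering
(later-painted crowns occlude earlier ones), matching how visually
confirmed reference crowns are drawn on real imagery. Ground-truth labels
for extracted objects come from the rasterized references: a segment takes
the majority crown's class when crowns cover ≥ 70 % of it, non-forest when
≤ 30 %, and is dropped as ambiguous in between — the rule-based stand-in
for the manual deletion of images "difficult to interpret"; the area
filter (min 600 px) likewise stands in for deleting fragments.

The default classification benchmark pools objects from three consecutive
seeded scenes (a small multi-area campaign), giving roughly 160–180
curated objects (~15–20 per tree class). What passing on this benchmark
shows — and what it does not: classes are separable by construction (colour
plus texture frequency), illumination is uniform, there are no
photogrammetric artefacts, shadows, understory bleed-through or seasonal
colour drift, and reference outlines are exact. Results on real imagery
depend on those factors and on the segmentation calibration transferring.

## Numerical choices and degenerate inputs

* Population (not sample) SD everywhere: defined for single-pixel segments.
* Merge threshold comparison is strict (`cost < scale**2`); the shape term
  may be negative in pathological geometries, which only ever makes a merge
  more admissible.
* GLCM windows smaller than every offset raise; a constant window yields
  the degenerate matrix (ASM = homogeneity = 1, contrast = dissimilarity =
  entropy = 0), and that equivalence is asserted as a biconditional.
* All-nodata DSMs, single-row DSMs, empty rasters, empty reference sets,
  non-adjacent merge requests, unnormalized matrices and out-of-range
  labels raise with explicit messages.
* Fill value for masked object backgrounds is 0 and the binary mask is
  retained, so no statistic ever ingests fill pixels.
* `np.unique` ordering relabels final segments 1..K by row-major first
  pixel, making label grids reproducible across runs.

## Known limitations

* The region merger optimises locally; no global objective is minimised,
  and segment-count monotonicity in `scale` is asserted empirically, not
  proven.
* GLCM features use a single pixel distance (1); multi-distance stacks and
  the remaining Haralick statistics are out of scope.
* The CNN is desk-scale; it demonstrates the protocol and powers the
  attention maps but is not a substitute for large pretrained backbones on
  real imagery.
* Polygonization builds pixel-edge polygons by unioning unit squares:
  exact (area equals pixel count) but not simplified; consumers wanting
  smooth outlines should simplify downstream.
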