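# Methods

## Problem setting

The package classifies every pixel of a georeferenced RGB orthoimage of a
river reach into one of twelve hydromorphological feature classes (side bar,
erosion, riffle, deep water, shallow water, tree, vegetated bar, vegetated
bank, submerged vegetation, emergent vegetation, grass, shadow), restricted
to the area inside the bank channel boundary. Classification is purely
colorimetric: no spatial context, texture descriptors or spectral bands
beyond RGB are used. That choice keeps the method transferable across
cameras and flights but makes classes that share chromaticity inherently
confusable — the package treats two such confusions (erosion vs shadow,
riffle vs shallow water) as first-class, reproducible phenomena rather than
defects.

## Coordinate contract

All rasters are square-pixel, north-up, in planar metres (CRS tagging is
metadata only; no reprojection is performed). Pixel (row, col) is 0-based
with row 0 at the north edge, and its centre maps to
`(origin_easting + (col+0.5)·gsd, origin_northing − (row+0.5)·gsd)`.
Nearest-pixel lookup rounds half-down on both axes, so points on a pixel
seam resolve deterministically to the smaller index. World files are read
and written with the ESRI convention (C/F lines hold the centre of the
top-left pixel); GeoTIFF georeferencing uses the ModelPixelScale and
ModelTiepoint tags with the tie point at the raster's outer corner.

## CIELAB transform

sRGB values are decompanded with the standard IEC 61966-2-1 curve and
converted through the sRGB→XYZ matrix to CIELAB under the D65 2° observer.
The white point is taken as the image of RGB = (1,1,1) under that same
matrix, which makes grey pixels map to a\* = b\* = 0 exactly rather than to
within the rounding of published D65 constants; the transform agrees with
scikit-image's `rgb2lab` to better than 0.02 on random colours. Downstream
clustering and (by default) classification use only (a\*, b\*): lightness
carries illumination, not material identity, and discarding it makes the
pipeline robust to uniform brightness changes. `L`-channel shifts provably
do not alter clustering output (tested).

## k-means on the chroma plane

Training-window pixels are clustered by Lloyd's algorithm on (a\*, b\*).
Seeding is deterministic: greedy farthest-point selection whose first point
comes from the run's seed. Empty clusters are repaired by re-seeding the
empty centroid at the point farthest from its assigned centroid. Because a
single Lloyd run is only a local optimiser, `lloyd_kmeans` makes `n_init`
(default 10) deterministic restarts with diversified seedings, and on small
inputs (≤ 256 k-subsets of distinct points) additionally starts one run from
every k-subset; the lowest-inertia solution is kept. In a 240-instance
stress test against exhaustive partition enumeration (n ≤ 8, k ≤ 3) this
reaches the global optimum in every case, whereas farthest-point restarts
alone missed it on about 5% of instances.

The iterative-k training loop runs k = 2…10, at each k exhaustively scoring
all 2^k − 1 cluster subsets by Jaccard overlap with the operator's reference
sketch, and stops at the first k whose best subset reaches the acceptance
threshold (default 0.8). This quantitative stopping rule stands in for the
visual "looks right" judgement of an interactive workflow: a union of
clusters is allowed because one feature commonly spans several shades. If no
k reaches the threshold the best result is returned flagged
`meets_threshold=False`.

## One-vs-rest perceptrons

Each class's classifier is a three-layer network: linear input combinations,
a sigmoid hidden layer (default 8 units), and a single sigmoid output node
trained to 1 on the class's pixels and 0 on pixels of every other class.
Training minimises the mean squared error with `scipy.optimize.minimize`
(BFGS, a quasi-Newton method) using analytic backpropagated gradients;
weights start uniform in (−0.5, 0.5) from the classifier seed.

Numerical choices that matter:

* **Input standardisation.** Features are shifted/scaled by the training
  set's mean and standard deviation (stored on the classifier). Raw (a\*, b\*)
  magnitudes (±60) would saturate the first sigmoid layer at initialisation.
* **Class-balanced loss.** Positive and negative samples each contribute
  half the total loss, so the decision threshold of 0.5 remains meaningful
  when the negative pool is much larger than the positive one.
* **Restarts.** MSE over saturating sigmoids has poor local minima in which
  a network "gives up" on one negative colour cluster (observed as a riffle
  network claiming vegetated-bank chroma). Training runs `n_restarts`
  (default 6) deterministic restarts and keeps the lowest final loss.
* **Logit-space merging.** When several confident networks all output
  activations that round to exactly 1.0 in float64, comparing activations
  degenerates into the tie-break. The multiclass merge therefore ranks
  networks by the output node's pre-sigmoid value, which orders identically
  (the sigmoid is strictly monotone) but never saturates. A pixel is
  labelled with the top-ranked class among those above threshold, 0
  (unclassified) if none passes; exact ties break by class-code order.
* **Feature space.** Default (a\*, b\*), matching the clustering space;
  (L\*, a\*, b\*) and raw RGB are selectable. The error function is MSE
  ("estimation error"); cross-entropy is deliberately not offered to keep
  the trained artefacts comparable.

Training sets are assembled per class from the cluster-built masks:
positives capped at 3000, negatives drawn evenly from the other classes
(two per positive, with a floor of 300 per competing class so that rare
classes still see every competing colour cluster).

## Tiled classification and areas

The orthoimage is split into a near-square grid of tiles (default 20; the
most balanced factorisation is used and the last row/column absorbs
remainder pixels). Tiles are classified independently and placed back by
pixel offset with no resampling, so the mosaic is bit-identical to a
single-tile run — tiling is purely a memory/throughput device and tiling
invariance is asserted in the tests. Areas are pixel counts times GSD²,
reported per class plus an explicit unclassified area; their sum equals the
in-boundary area exactly, in pixel units.

## Validation

A lattice anchored at the minimum corner of the boundary extent (inclusive
of both edges when they land on the lattice) is filtered by the boundary
mask; each surviving point samples the map by nearest pixel. On the map side
the five non-tree vegetation classes merge into one VG category (trees stay
separate), mirroring how a map is read at survey scale. The confusion matrix
is truth classes × merged categories, with a GE column populated only when
tile-misalignment fault injection has flagged seam points and an NC column
only when unclassified pixels are sampled.

Per class: TP is the count in the class's own category column; FN the rest
of its row; FP the rest of its column; TN the remainder of the grand total.
The tree class counts tree-row points predicted VG as additional TP —
canopy recognised as vegetation but not attributed to the tree layer — a
convention that is switchable (`tree_vg_as_tp`). Undefined ratios (a class
absent from truth, or no negatives) are reported as `None`, never 0 or 1.

Overall accuracy `ac` is the fraction of grid points whose category matches
their truth class — the operational meaning of "points classified
correctly". The accuracy formula evaluated on pooled one-vs-rest tallies is
also reported (`ac_pooled`) but is not the headline number: with merged
categories it double-counts within-vegetation confusions. On the bundled
reference survey matrix the diagonal convention yields 77.1%, whereas the
original survey reported 81%; no documented counting convention reproduces
the latter from the printed matrix, and the package makes no attempt to.
The printed TNR/FNR columns of that survey are likewise inconsistent with
the ratio definitions applied to the printed matrix (e.g. deep water TNR
0.741 printed vs ≈0.99 recomputed); only the TPR column is reproduced.

Coregistration error is RMSE = √(Σ[(x̂−x)² + (ŷ−y)²]/N) over control-point
pairs, filterable by role (GCP vs independent check points), with per-axis
mean absolute errors. Under iid Gaussian per-axis offsets of sd σ the
expected RMSE is σ√2, which the synthetic recovery tests exploit.

## Synthetic scenes

The generator renders a sine-meander channel on a default 1000 × 800 grid at
2.5 cm GSD: a deep-water core inside shallow margins, riffle bands spanning
the wetted width, gravel bars on inner bends (partly vegetated), vegetated
banks with erosion strips on outer bends, grass beyond, canopy disks with
south-west cast shadows, and submerged/emergent vegetation patches in the
margins. Geometry is solved from requested class fractions (default: deep
water 0.16, shallow water 0.12, riffle 0.09, side bar 0.035, vegetated bar
0.02, vegetated bank 0.09, erosion 0.012, tree 0.05, shadow 0.02, submerged
0.018, emergent 0.008, grass the remainder); realised truth fractions land
within ±0.02 of the request on the default size. Everything is deterministic
given the `SceneSpec` (seed included), to the bit.

Colours were chosen by a design-stage separability analysis on the (a\*, b\*)
plane: all class pairs are ≥ 11 units apart except (i) pairs within the
merged vegetation category, where confusion is harmless; (ii) erosion vs
shadow; and (iii) riffle vs shallow water — riffle shares the shallow-water
base colour and becomes separable only through its ripple texture, which
mixes pixels 40–75% towards a pale warm foam colour (245, 250, 210). Tree
canopy carries a multiplicative luminance speckle. Pixel noise is iid
Gaussian per channel (sd 3 digital numbers), clipped to [0, 255]. The two
engineered overlaps reproduce the field failure modes in kind: darkening
erosion towards shadow collapses erosion recall, and removing ripple texture
reclassifies riffle as shallow water.

What the generator does **not** emulate: gradual class transitions
(boundaries are crisp), within-class colour gradients, sun-angle-dependent
shadow geometry, water-depth-dependent colour, sensor vignetting, or
photogrammetric artefacts beyond optional rigid tile shifts
(`inject_tile_misalignment`, which also flags seam points for the GE
accounting path). Passing end-to-end tests therefore demonstrates the
pipeline's correctness and its behaviour under controlled colour overlap —
not field-grade accuracy on real imagery, where transitions and lighting
make all classes harder.

## Benchmark problem sizes

The end-to-end benchmark trains on scene A and validates on an independently
seeded scene B of the same size (default 1000 × 800 px = 25 m × 20 m).
Validation uses a 0.4 m grid — the package's scaling of the 2 m field
protocol to a reach two orders of magnitude shorter — giving ≈ 2,200 points
with double-digit counts in the rarest class. Qualitative-behaviour checks
run at 760 × 600 with pixelwise recall over the affected class, which is
more stable than grid counts for classes occupying ~1% of the scene.

## Known limitations

* Purely per-pixel chromatic classification; no spatial regularisation is
  applied (and none is offered), so salt-and-pepper errors appear near class
  boundaries on noisy imagery.
* The "visually satisfactory" clustering stop is operationalised as a
  Jaccard threshold against an operator sketch; a poor sketch degrades the
  training set silently (the below-threshold flag is the only warning).
* Multi-restart BFGS makes training deterministic but not convex: a class
  whose chroma cloud is non-convex and adjacent to a competitor may still
  train to a generous boundary on an unlucky seed.
* All coordinates are planar metres; inputs in different CRSs must be
  harmonised upstream.
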