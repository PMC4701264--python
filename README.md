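# hydromorph

Automated mapping of river hydromorphological features from high-resolution
UAV RGB orthoimagery.

Hydromorphology — the physical make-up of a river channel: substrate units,
flow units and riparian vegetation — underpins ecological status assessment,
but walk-over surveys are slow, subjective and hard to repeat. `hydromorph`
implements a supervised pixel-classification framework for centimetre-scale
(≈2.5 cm ground sample distance) orthoimages of river reaches. It is aimed at
river scientists and agency surveyors who have a georeferenced orthomosaic,
a channel boundary, and a little operator effort to spare for training, and
who want a classified feature map, per-class areas, and a defensible accuracy
assessment.

## Method

Twelve feature classes are mapped: side bars, erosion, riffle, deep water
(glides and pools), shallow water, trees, vegetated bars, vegetated banks,
submerged and emergent free-floating vegetation, grass, and shadow.

1. **Colour space.** Imagery is converted from sRGB to CIELAB (D65). Only the
   chromatic axes (a\*, b\*) are used downstream, making the classification
   insensitive to uniform illumination changes.
2. **Cluster-assisted training.** For each class an operator selects a small
   window where the feature fills at least half the area, plus a rough
   reference sketch. The window is clustered by k-means on (a\*, b\*) with k
   increased from 2 up to 10 until the union of clusters best matching the
   sketch reaches a Jaccard overlap of 0.8. Those pixels become the class's
   training sample.
3. **One-vs-rest neural networks.** Each class gets a three-layer perceptron
   (input → hidden → single sigmoid output) trained to 1 on its own pixels
   and 0 on all others, by quasi-Newton (BFGS) minimisation of the mean
   squared error with backpropagated gradients.
4. **Tiled mapping.** The full orthoimage is processed in tiles (20 by
   default) and reassembled losslessly; per pixel, the class of the highest
   network output among those above threshold wins, giving a single labelled
   map and per-class areas (pixel count × GSD²).
5. **Validation.** A regular grid (2 m spacing at field scale) is overlaid on
   the map; grid categories are compared with visually classified ground
   truth in a confusion matrix, from which overall accuracy AC and per-class
   ratios are derived:

   TPR = TP/(TP+FN), TNR = TN/(TN+FP), FNR = FN/(TP+FN), FPR = FP/(TN+FP).

   Georeferencing quality is quantified by the control-point RMSE
   √(Σ[(x̂−x)² + (ŷ−y)²]/N) over ground-control or independent check points.

Because no survey imagery is distributable, the package includes a synthetic
scene generator that renders a meandering channel (deep-water core, shallow
margins, rippled riffle bands, bars, banks, erosion strips, canopy with cast
shadows, vegetation patches) with wall-to-wall truth labels, truth grids and
control points, so the entire pipeline is testable end to end.

## Worked example

The package bundles the confusion matrix of a reference field survey
(13,085 grid points over a 1.4 km reach). Running the metric arithmetic:

```python
from hydromorph import example_survey_confusion, metrics, FeatureClass

report = metrics(example_survey_confusion())
print(f"points: {report.n_points}   overall accuracy: {report.ac:.3f}")
for cls in (FeatureClass.DEEP_WATER, FeatureClass.RIFFLE, FeatureClass.EROSION):
    m = report.per_class[cls]
    print(f"{cls.name.lower():<12} TPR={m.tpr:.3f}  FNR={m.fnr:.3f}  (TP={m.tp}, FN={m.fn})")
```

prints

```
points: 13085   overall accuracy: 0.771
deep_water   TPR=0.926  FNR=0.074  (TP=1927, FN=155)
riffle       TPR=0.814  FNR=0.186  (TP=2717, FN=622)
erosion      TPR=0.077  FNR=0.923  (TP=22, FN=265)
```

Deep water is recovered reliably (92.6% of its truth points), riffle well
(81.4%), while erosion — vertical cut banks barely visible from above, and
coloured like shadow — is largely missed, the canonical hard case. Overall,
77.1% of the grid points carry the correct label. A full synthetic round
trip (train on scene A, classify an independently generated scene B):

```python
from hydromorph import run_benchmark, FeatureClass

res = run_benchmark(seed=1, height=600, width=760)
rep = res.report
print(f"grid points: {rep.n_points}   accuracy: {rep.ac:.3f}")
for cls in (FeatureClass.RIFFLE, FeatureClass.DEEP_WATER, FeatureClass.GRASS):
    print(f"{cls.name.lower():<12} TPR={rep.per_class[cls].tpr:.3f}")
```

```
grid points: 1322   accuracy: 0.992
riffle       TPR=0.986
deep_water   TPR=0.993
grass        TPR=0.996
```

The same loop is available from the shell:

```bash
hydromorph simulate --seed 3 --out run/sim
hydromorph train    --image run/sim/ortho.tif --regions regions.yaml --out run/model
hydromorph classify --image run/sim/ortho.tif --model run/model/bundle.json \
                    --tiles 20 --out run/cls
hydromorph validate --map run/cls/map.tif --truth run/sim/truth_points.csv \
                    --out run/val
hydromorph report   --run run/val
```

Every subcommand writes a `manifest.json` (config echo, seeds, input
checksums) alongside its outputs.

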