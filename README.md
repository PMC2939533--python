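# fuzzywater

Fuzzy-edge / watershed analysis of 3D brain perfusion volumes, with
parietal region-of-interest (ROI) region counting and a region-count
threshold classifier.

## The problem

On brain perfusion SPECT, Alzheimer's disease (AD) shows reduced regional
cerebral blood flow in the temporo-parietal cortex. Visual reading of such
scans has limited sensitivity and specificity. `fuzzywater` implements an
automated analysis that turns a raw 3D scan into a single interpretable
number — the count of watershed-separated activity regions inside two
parietal ROI boxes — and classifies subjects by thresholding that count:
AD-like perfusion produces *fewer* distinct activity domains in the
parietal lobes than cognitively normal perfusion.

It is intended for researchers in nuclear-medicine image analysis who want
a reproducible, dependency-light reference implementation of this pipeline
together with the study machinery (cross-validated parameter tuning,
confusion statistics, group comparison) and a synthetic phantom generator
that makes the whole method testable without clinical data.

## The method

Each volume `I` passes through six consecutive operations:

1. **Gaussian smoothing** — isotropic 3D Gaussian, standard deviation *r*
   (voxels), the first tunable parameter.
2. **Normalization** — division by the global maximum, so intensities lie
   in (0, 1] with 1 = maximum brain activity.
3. **Background elimination** — soft thresholding against θ ∈ (0, 1):
   `v ← max(v − θ, 0)` (the positive difference is passed; negative
   differences become zero).
4. **Fuzzy edge detection** — intensities are fuzzy truth values; the
   fuzzy equivalence of neighbors x, y is the Łukasiewicz bi-residuum
   `x ↔ y = min(1 − x + y, 1 − y + x) = 1 − |x − y|`, its negation
   `1 − (x ↔ y) = |x − y|` the non-equivalence. Each voxel's edge
   intensity is the fuzzy OR (maximum) of the non-equivalences with its
   six face neighbors, giving a volume of fuzzy edges that traces maximal
   morphological gradients of activity.
5. **3D watershed** — the edge volume is segmented into the catchment
   basins of its local minima (6-connected steepest descent), with
   one-voxel-thick watershed lines (label 0) marked on inter-basin ridges.
6. **ROI region counting** — the number of distinct basins intersecting
   the union of two mirrored 22×29×3-voxel parietal boxes.

A subject with count ≤ cutoff *c* is classified AD-like (AD is the
positive class). The triple (r, θ, c) is tuned by leave-one-out
cross-validation maximizing Youden's index on each training fold; group
count means are compared with a pooled two-sample Student t-test, and
sensitivity/specificity carry exact Clopper–Pearson 95% intervals.

## Worked example

Generate a small synthetic cohort (3 AD-like subjects with 4 parietal
activity peaks per side, 3 control-like with 10 per side, 64³ voxels),
run the pipeline, and cross-validate:

```bash
$ cat cfg.yaml
cohort: {n_ad: 3, n_control: 3, shape: [64, 64, 64]}
grid:   {radii: [0.7, 0.9, 1.1], thresholds: [0.2, 0.3, 0.4]}

$ fuzzywater phantom --config cfg.yaml --out cohort --seed 1
$ fuzzywater pipeline cohort/manifest.csv --radius 0.9 --threshold 0.3 --out counts.csv
subject_id   group  count_total  count_left  count_right
      AD01      AD           14           7            8
      AD02      AD           13           7            7
      AD03      AD           14           7            8
 control01 control           36          15           22
 control02 control           34          15           20
 control03 control           29          18           12
$ fuzzywater loocv cohort/manifest.csv --config cfg.yaml --out cv.json --seed 1
$ fuzzywater report --cv cv.json
LOOCV over 6 folds
  smoothing radius: 0.7000 +/- 0.0000
  background threshold: 0.3000 +/- 0.0000
  region-count cutoff: 18.5000 +/- 0.3416
out-of-sample: TP=3 FP=0 TN=3 FN=0
  sensitivity 100.0% [29.2, 100.0]
  specificity 100.0% [29.2, 100.0]
final (mean parameters): TP=3 FP=0 TN=3 FN=0
  sensitivity 100.0% [29.2, 100.0]
  specificity 100.0% [29.2, 100.0]
  t-test: t = 13.096, df = 4, p = 0.000196
```

AD-like phantoms yield region counts around 13–14 versus 29–36 for
control-like phantoms, every fold selects essentially the same parameters
(the derived cutoff 18.5 ± 0.34 is the midpoint of the training-group
means), every held-out subject is classified correctly, and the pooled
t-test rejects equality of the group mean counts.

The same workflow is available as library calls
(`fuzzywater.generate_cohort`, `fuzzywater.process_volume`,
`fuzzywater.loocv_tune`, …); the region-count classifier is a
scikit-learn estimator (`fuzzywater.RegionCountClassifier`).

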