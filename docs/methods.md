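# Methods

## Pipeline model and assumptions

The package analyzes a single 3D scalar volume of perfusion activity
(nonnegative counts on a regular voxel grid, axis convention x =
left–right, y = posterior–anterior, z = inferior–superior, 0-based
indices). No spatial registration, attenuation handling or acquisition
modeling is attempted: the method consumes reconstructed volumes as-is and
relies only on *local intensity structure*, which is what the six-stage
pipeline extracts.

1. **Gaussian smoothing.** The "radius" parameter is interpreted as the
   standard deviation σ of an isotropic 3D Gaussian in voxel units —
   the only convention under which values near 0.9 give visible but mild
   smoothing on unit-spaced voxels. The kernel is normalized to unit sum
   and truncated at 4σ (half-width `int(4σ + 0.5)`); boundaries are
   handled by reflection, so constant volumes pass through exactly.
2. **Normalization** divides by the global maximum. After smoothing the
   global maximum lies inside the brain for any realistic scan, so no
   brain mask is needed at this stage. The stage order (smooth, then
   normalize, then threshold) is fixed and order-sensitive.
3. **Background elimination** is soft thresholding: `max(v − θ, 0)` with
   θ ∈ (0, 1). The *difference* is passed, not the original value, so the
   output range is [0, 1 − θ].
4. **Fuzzy edge detection.** Two algebraically identical routes are
   implemented: the literal Łukasiewicz construction (bi-residuum →
   fuzzy negation → max aggregation) and the closed form
   max over face neighbors of |Δ|. The literal route is the reference,
   the closed form the default fast path, and tests assert their
   equality — a built-in oracle. Boundary voxels aggregate over their
   available (< 6) neighbors only; padding would fabricate edges at the
   volume faces. A 1×1×1 volume has no neighbors and is rejected.
5. **Watershed.** The transform follows the classical
   basins-of-attraction definition: every voxel descends to the
   6-connected local-minimum plateau reached by steepest descent, and
   each minimum plateau seeds one basin. Watershed lines are then marked
   as label 0 on inter-basin ridges: of every face-adjacent pair in
   different basins, the higher-valued voxel is marked (equal values:
   the voxel later in scan order), giving a one-voxel-thick deterministic
   border set that never includes a seed. Determinism is total: descent
   ties use the fixed neighbor order (−x, +x, −y, +y, −z, +z); draining
   (non-minimum) plateaus are resolved by a layered frontier sweep from
   their exits; basins are labeled 1..K in scan order of their seed's
   smallest flat index. Basin count and partition are invariant under any
   strictly monotone transform of the edge intensities. The
   implementation is vectorized (lowest-neighbor pointers, plateau
   components via an equal-value adjacency graph, pointer doubling),
   which keeps a 128³ transform in the seconds range.
6. **Region counting** reports the number of distinct basin labels
   (≥ 1) intersecting the union of the left and right ROI boxes, plus
   per-side counts for transparency; line voxels never count. Counting
   the union avoids double-counting a basin that straddles both boxes.

## ROI geometry

The ROI boxes default to 22×29×3 voxels per parietal lobe; no
standard coordinates or atlas exist for their placement on unregistered
scans. The defaults place the left box center at fractional
position (0.30, 0.62, 0.55) of the volume shape — a posterior-superior
lateral position consistent with the parietal lobe in a canonical
RAS-oriented volume — and mirror the right box exactly about the
mid-sagittal plane, so the default pair is disjoint and
reflection-symmetric. Centers and extents are overridable via config.
Boxes are half-open; a box that does not fit the volume is an error,
never a silent clip.

## Classification and statistics

A count at or below the cutoff is AD-like (ties favor the positive
class, i.e. sensitivity; with a non-integer cutoff no integer count ever
ties). Sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP), with
95% Clopper–Pearson (exact) intervals by default — standard for samples
of this size; Wilson and normal intervals are selectable. The group
comparison is the two-sided pooled-variance Student t-test (Welch
available as an option), reported with t, df, p, group means/SDs, t-based
mean CIs and chi-square-based SD CIs. A zero pooled variance with unequal
means raises an overflow error rather than reporting an infinite t.

## Leave-one-out tuning

The per-fold objective is Youden's index (sensitivity + specificity −
100) of the threshold classifier on the training subjects, maximized over
a grid of (radius, threshold) pairs; ties resolve to the smaller radius,
then threshold, then cutoff. The cutoff is either searched on an explicit
grid or, by default, *derived* per candidate grid point as the midpoint
between the two training-group mean counts — a continuous critical count
whose across-fold spread is naturally small when the groups separate
well. Because the pipeline maps each subject to its count independently
of all others, the subject × grid-point count table is computed once and
folds only re-read it; this is leakage-free (verified by a perturbation
test) and makes LOOCV cost one pipeline run per subject per grid point.
After the folds, the whole cohort is re-classified at the across-fold
mean parameters ("final" metrics); this evaluation is in-sample by
construction and is reported as such, alongside the honest out-of-sample
fold metrics.

The package default grid spans radii 0.5–1.5 (step 0.1) and thresholds
0.10–0.50 (step 0.05). The desk-scale validation study uses the coarser
bracket radii {0.7, 0.9, 1.1} × thresholds {0.2, 0.3, 0.4} with derived
cutoffs, keeping the full study in the tens of seconds on one CPU.

## The phantom generator

A phantom is an ellipsoidal brain support (semi-axes 0.42/0.46/0.40 of
the shape) at baseline activity 1, plus isotropic Gaussian activity
peaks: `n_peaks_parietal` per side sampled uniformly inside each parietal
ROI box and `n_peaks_elsewhere` (default 20) inside the rest of the
brain, with all centers rejection-sampled to be pairwise ≥ 3·max(σ)
apart (σ ~ U(1.2, 2.0) voxels). AD-like subjects receive fewer parietal
peaks (default 4/side) than control-like subjects (default 10/side) —
the construction that makes AD-like region counts lower, emulating
parietal hypoperfusion. Additive Gaussian noise (default σ = 0.05, i.e.
5% of baseline) or scaled Poisson noise is applied last and the volume
clipped at zero. Per-subject seeds are master seed + subject index; a
fixed seed reproduces a cohort bitwise.

Peak amplitudes default to U(2.0, 4.0) × baseline. This severalfold
contrast of focal cortical activity over nonspecific background is what
makes the background-elimination stage effective: after normalization the
inter-peak baseline sits near 0.25, below attainable thresholds, so
thresholding suppresses the noisy inter-peak floor and the watershed
count tracks activity-peak multiplicity. With peak amplitudes comparable
to baseline, the normalized baseline (~0.5) survives every threshold and
counts are dominated by noise-field minima — a regime in which the count
no longer reflects peak structure and the generator would fail its
purpose.

What the phantom does *not* emulate: anatomy (no gray/white structure,
no atlas), acquisition physics (no projection/reconstruction, no
attenuation, no spatially correlated reconstruction noise), and
partial-volume effects. Passing the synthetic study therefore shows that
the pipeline recovers controlled differences in local activity-peak
structure under noise; it does not certify clinical performance.

## Validation study and problem sizes

The packaged validation study (shared by the test suite and
`scripts/acceptance.py`) uses 64³ phantoms, 10 AD-like vs 10
control-like subjects, the desk-scale grid above, and a fixed master
seed. Typical outcome: AD-like counts ≈ 10 ± 4 vs control-like ≈ 34 ± 8,
pooled t ≈ 9 (p ≈ 5×10⁻⁸), LOOCV out-of-sample sensitivity and
specificity 100%, derived cutoff stable across folds (SD ≈ 0.3). The
t-test's empirical type-I error over 10,000 same-distribution pairs sits
at the nominal 5% within binomial error. 128³ volumes are supported
throughout and used in the round-trip tests; the study runs at 64³ as
the package's desk-scale preset.

## Numerical choices and degenerate inputs

- Volumes are float64 end to end; NIfTI output is written as float64 with
  an identity affine, so write→read round-trips are exact.
- All-zero volumes cannot be normalized (error); non-3D, non-finite or
  negative input volumes are rejected at the boundary, never repaired.
- Edge-detection inputs must lie in [0, 1] (tolerance 1e-12 at the top).
- Grid-search tie comparisons use a 1e-9 margin so exact Youden ties keep
  the first (smallest-parameter) candidate.
- Every stochastic component takes an explicit seed; everything else is
  deterministic by construction, and the CLI workflow reproduces its CSV
  and JSON outputs byte for byte.

## Known limitations

- ROI placement is a documented default, not a validated anatomical
  claim; real studies should supply coordinates.
- The watershed deliberately applies no over-segmentation merging; on
  noise-dominated inputs (weak smoothing, low threshold) counts can be
  large and uninformative — parameter tuning is part of the method.
- The final fixed-parameter metrics are in-sample; only the fold-wise
  metrics estimate out-of-sample performance.
- Welch's correction and alternative proportion CIs are provided but the
  defaults (pooled t, Clopper–Pearson) are what the reported numbers use.
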