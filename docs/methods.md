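# Methods

`arterylabel` re-implements a fully automated anatomical labelling pipeline
for cerebral arterial trees: a binary angiographic volume goes in, and every
point of the arterial centerline comes out tagged with one of 62
conventional branch identifiers grouped into 20 anatomical chunks.  Because
no public cohort accompanies the method, the package ships a first-class
synthetic generator of Circle-of-Willis-like arterial phantoms on which the
whole pipeline is exercised and validated.

## 1. Vascular unit hierarchy

The vasculature is reframed into four levels:

* **spot** — a centerline point sampled every 0.2801 mm, carrying a
  12-dimensional predictor vector (3 normalised coordinates + 9 geometric
  features);
* **segment** — a contiguous run of spots between bifurcations (one
  junction-to-junction or junction-to-endpoint centerline);
* **branch** — one of 62 conventionally named arteries, identified as
  `<chunk>.<2-digit>` (e.g. `A7.09`); chunks owning a single branch (ACOA
  `A0`, basilar `P0`, vertebrals `P1`/`P2`) use their bare chunk code;
* **chunk** — one of 20 functional-anatomical groupings (`A0`–`A10`
  anterior, `P0`–`P8` posterior; odd serial = right, even = left).

The full 62-code table ships as an editable JSON resource
(`arterylabel/data/nomenclature.json`).  The sided chunk structure and every
code referenced by convention are fixed; a few segment-digit memberships
that convention does not pin down are marked `provisional` in the resource
and can be re-mapped without code changes.

## 2. Geometric characterisation

1. **Isovoxel resampling.**  Anisotropic inputs are resampled to the
   finest-axis isotropic grid by bicubic interpolation of the occupancy and
   re-binarisation at 0.5.  The default synthetic grid is already isotropic
   at 0.284 mm.
2. **Skeletonisation.**  3-D thinning (Lee's method) per connected
   component, assembled into a 26-connectivity voxel graph.  The inscribed
   radius at every skeleton voxel is the distance to the nearest
   foreground-adjacent background voxel — mathematically identical to
   evaluating the Euclidean distance transform there, but computed sparsely
   with a KD-tree.  One guard exists for perfectly voxel-symmetric objects
   (possible only with analytic phantoms), whose thinning can collapse to
   nothing: the surface is lightly and deterministically roughened for the
   thinning step only.
3. **Pruning.**  Leaf paths shorter than `max(prune_mm, 2.4 × inscribed
   radius at the junction)` are removed shortest-first until a fixed point;
   a component is never pruned below two endpoints.  The radius-scaled term
   removes thinning spurs at thick-trunk take-offs (spur artifacts scale
   with vessel calibre); `prune_mm` defaults to 2.0 mm and is configurable.
4. **Rooting and cycle breaking.**  Per component the root is the skeleton
   voxel on the lowest slice (ties by smallest x, y).  Cycles — thinning
   artifacts at thick junctions, or anastomoses in real data — are broken
   by a maximum spanning tree on local inscribed radius, so the cut lands
   on the thinnest vessel of each loop.
5. **Centerlines.**  Junction-to-junction paths (adjacent junction voxels
   merged per anatomical bifurcation) are smoothed by a short moving
   average plus a cubic smoothing spline (residual scale 0.2 mm, about the
   voxel quantisation error); tangents use a ±1 mm central-difference
   baseline.  Terminal tips are prolonged along the end tangent to the
   foreground boundary, compensating the ≈ one-radius tip retraction
   inherent to thinning.  Without the spline and the wide tangent baseline,
   voxel-scale zig-zag dominates curvature estimates (≈ 0.04 mm⁻¹ of pure
   noise on a straight tube); with them a straight phantom measures
   ≈ 0.002 mm⁻¹.

### Features per spot

Cross-sections are measured on a plane normal to the local tangent,
resampled at half-voxel pitch.  The connected in-plane region containing
the spot gives: area (pixel count × pitch²), circumference (sub-pixel
marching-squares contour length, after a light in-plane Gaussian blur of
σ = 0.6 px that removes the voxel staircase from the 0.5 level-set),
min/max caliper diameters (extent of the contour projected onto 1°-stepped
directions) and radius ratio (max/min).  The remaining features are the
inscribed radius (centerline annotation), distortion (arc/chord over a
5 mm window; one-sided at polyline ends), curvature (finite difference of
window half-chord tangents over the same window) and circularity
(isoperimetric 4πA/P², capped at 1.05 because pixel-count area bias can
push lumens a few pixels wide past the analytic bound; a hydraulic 4A/P
variant is available via `circularity_mode`).

Spot coordinates fed to the classifier are normalised per subject — centre
of foreground mass subtracted, scaled by the foreground bounding-box
diagonal — so the features are invariant to rigid translation and robust
to unregistered inputs.

## 3. Two-step classification

* **Split.** Always by subject, never by spot; `round(0.7·n)` subjects
  train, the rest test, stratified by cohort; the feature scaler is fitted
  on training subjects only.
* **Step 1 (spot → chunk).** A multilayer perceptron (two hidden layers
  64/32, ReLU, adaptive-moment optimiser, early stopping with patience 10)
  over the 12 standardised predictors.  Class imbalance (the ACOA class is
  tiny) is handled by bounded inverse-frequency oversampling toward the
  median class count (cap 4×), since the MLP implementation accepts no
  class weights.
* **Voting.**  Every segment's spots adopt the segment's modal label; ties
  break by the highest summed predicted probability, then lexicographically
  — fully deterministic.  The closed-form oracle for iid spot errors is the
  binomial majority tail (with even splits counted half).
* **Step 2 (spot → branch).** One MLP per chunk owning several branches,
  trained on that chunk's spots and applied within the voted step-1 chunk
  assignment, followed by another voting round.  Single-branch chunks are
  assigned deterministically.  The emitted branch always satisfies
  `chunk_of(branch) = chunk`.
* **Anatomical post-processing** (optional, on by default; both rules are
  explicit, conservative stand-ins and can be disabled per rule):
  * *connectivity* — a non-terminal segment forming a singleton island of
    its chunk, while a connected body (≥ 2 segments) of that chunk exists
    elsewhere in the subject, adopts its tree-neighbours' modal chunk.
    Terminal segments are exempt (leaves legitimately dangle into foreign
    territory), as are chunks that only occur as single segments.
  * *laterality* — a segment labelled with a sided chunk but lying > 12 mm
    on the wrong side of the subject's mid-sagittal plane (foreground
    centre of mass; right = +x in the synthetic frame) flips to the mirror
    chunk and mirror branch.
  Both rules iterate to a fixed point, making the pass idempotent.

## 4. Synthetic cohorts

The generator is the package's study population, so its defaults are fixed
conditions, not tuning dials.

* **Topology.**  A hard-coded 62-branch forest with three roots (right and
  left ICA, right vertebral carrying the vertebrobasilar system);
  communicating arteries are terminal branches of one side so the
  structure remains a forest.  Most children attach at their parent's
  distal tip (a bifurcation); a few (ophthalmic, choroidal, PICA, SCA,
  PCOA, `A7.09`) attach at interior fractions.
* **Geometry.**  Each branch is a circular-arc drift plus an out-of-plane
  sinusoid, rescaled so realised arc length matches the drawn length
  within 1%; radii taper linearly.  Branch azimuths are measured in the
  parent's parallel-transported frame, which is stable along curved
  vessels and mirror-consistent between sides (branch azimuths mirror as
  φ → 180° − φ; root curl axes as φ → −φ).  The layout is schematic, tuned
  so that non-adjacent branches keep ≥ ~0.7 mm surface clearance across
  seeds — a collision would fuse the voxelised trees and destroy the forest
  topology.
* **Per-subject variation.**  Presence probabilities (ACOA ≈ 0.6, distal
  branches 0.3–0.8, trunks 1.0), truncated-Gaussian lengths (8% SD) and
  radii (6% SD), jittered branching angles, a global scale factor
  (SD 4%) and a ±5° axial rotation.  Children at cross-chunk bifurcations
  are always present so chunk boundaries stay bifurcation-delimited;
  when presence sampling removes one of two same-chunk siblings, the
  survivor smoothly continues its parent and the bifurcation genuinely
  disappears — the topology oracle accounts for this.
* **Cohorts.**  `control`: as above.  `icas`: one or two
  stenosis (severity 0.55–0.9 on a contiguous radius window) or occlusion
  (subtree removal) events on major arteries, plus a 0.85 distal presence
  multiplier.  `stroke`: a milder mixture.  Expected control profiles are
  ≈ 3,600 spots, ≈ 50 segments and ≈ 19 chunks per subject; ICAS subjects
  lose whole chunks through occlusion.  The spot density sits in the lower
  half of the thousands-per-subject range typical of clinical trees: the
  centerline length that would push it higher cannot be packed into a
  head-sized bounding box at realistic tortuosity without branch
  collisions, so total length ≈ 1 m per subject was chosen and is fixed.
* **Voxelisation.**  A voxel is foreground iff its centre lies within the
  local tube radius of some centerline point (the union of balls along the
  line — a capsule, including hemispherical end caps); its label is the
  branch of the nearest covering point.  Branches thinner than half a
  voxel trigger a warning and may vanish from the raster.

### What the phantoms do not emulate

No imaging physics (no intensity, noise, partial-volume or flow
artifacts), no contact between arteries and surrounding anatomy, no true
anastomotic loops, and schematic rather than anatomically exact courses.
Passing tests therefore demonstrate the correctness of the geometric and
learning machinery under known ground truth — not clinical performance on
MRA data.

## 5. Evaluation

Per-class precision/recall/F1 are one-vs-rest; "accuracy" is reported both
as one-vs-rest accuracy and as within-class recall, since conventions
differ.  AUROC/AUPRC use one-vs-rest curves with micro (pooled) and macro
(class-mean over supported classes) averages.  Groupwise statistics are
two-sample t and one-way F tests on subject-level feature means per
(chunk, feature), masked at p > 0.001.  An optional stratified bootstrap
(2,000 seeded resamples within classes) provides a 95% CI for the micro
AUROC.  Cluster separability embeds the
12 predictors with UMAP (fixed seed) and scores the mean silhouette at
chunk and branch colouring on the same embedding; the package asserts only
the direction (chunk > branch).  The voting significance test is a
one-sided sign-flip permutation over per-segment paired correctness
indicators (subject-level pairing at the default cohort size cannot reach
p < 0.001 by construction).

## 6. Problem sizes and determinism

The documented experiment uses 30 control subjects (70/30 split) plus 8
ICAS-like external-validation subjects at 0.284 mm spacing — roughly 110k
training spots — and completes in well under half an hour on one CPU.  All
randomness flows from one root seed through named substreams
(`simulate/<cohort>/<k>`, `split`, `mlp`, `umap`, `permutation`); identical
configurations reproduce identical reports, and every artefact carries the
resolved configuration hash.

## 7. Known limitations

* Segment-level ground truth is voxel-derived; merged parent–child
  segments (a vanished sibling) mix two branch labels, which bounds
  branch-level voting accuracy from above.
* The spur-pruning radius factor (2.4×) and the smoothing-spline residual
  (0.2 mm) are voxel-scale heuristics validated on phantoms at 0.28 mm
  spacing; substantially coarser rasters may need re-tuning.
* The anatomical post-processing rules are deliberately conservative; they
  repair isolated interior mislabels and gross lateral flips only.
* Real-data performance figures (accuracy on clinical cohorts) are out of
  scope: no public cohort exists for this task, and the synthetic cohorts
  are stand-ins with known ground truth.
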