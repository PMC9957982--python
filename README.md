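# arterylabel

Automated anatomical labelling of cerebral arterial trees from binary
angiographic volumes.

Identifying which artery every piece of a segmented cerebrovascular tree
belongs to — internal carotid, M1, angular MCA, pericallosal ACA, … — is a
prerequisite for quantitative cerebrovascular research, and doing it by
hand is slow and observer-dependent.  `arterylabel` implements a fully
automated pipeline aimed at neuroimaging researchers working with
time-of-flight MRA segmentations:

1. **Geometric characterisation** — isovoxel resampling, 3-D thinning to a
   skeleton graph, pruning, rooting and cycle-breaking into a forest, and
   radius-annotated centerline extraction.
2. **Hierarchical reframing** — *spots* (centerline points every
   0.2801 mm) → *segments* (between bifurcations) → 62 *branches*
   (conventional arterial nomenclature, e.g. `A7.09`) → 20 *chunks*
   (anatomical groupings such as "right anterior pial MCA").
3. **Nine geometric features per spot** — cross-sectional area, maximally
   inscribed sphere radius, min/max caliper diameter, max/min radius
   ratio, circumference, distortion (arc/chord tortuosity), curvature, and
   hydraulic/luminal circularity — plus the normalised spatial
   coordinates: 12 predictors in total.
4. **Two-step classification** — a multilayer perceptron allocates each
   spot to a chunk (step 1), per-chunk MLPs allocate spots to branches
   (step 2), and segment-wise majority voting plus anatomical
   post-processing (connectivity and laterality rules) clean up the
   labels.  The chunk-level label of a segment with spots voting
   `{A7, A7, A3}` becomes `A7` everywhere.
5. **Evaluation** — per-class precision/recall/F1, micro/macro AUROC and
   AUPRC, groupwise t/ANOVA feature statistics (p ≤ 0.001), and UMAP
   silhouette separability at chunk vs branch level.

No public cohort exists for this task, so the package also contains a
first-class **synthetic vascular tree generator**: Circle-of-Willis-like
62-branch forests with per-subject anatomical variation, ACOA instability,
and ICAS-like stenosis/occlusion pathology, voxelised into paired
occupancy + ground-truth label volumes (NIfTI).  The full pipeline is
validated end-to-end against this known ground truth; see
`docs/methods.md` for the model, assumptions and limitations.

## Worked example

```python
from arterylabel import (NomenclatureMap, RunConfig, run_experiment)

config = RunConfig(seed=5, n_control=6, n_icas=2)
results = run_experiment(config, "out/")
ctl = results["control"]
print(f"chunk spot accuracy (voted): {100*ctl['chunk_spot_accuracy_voted']:.1f}%")
print(f"segment accuracy (voted):    {100*ctl['segment_accuracy_voted']:.1f}%")
print(f"micro AUROC:                 {ctl['auroc_micro']:.3f}")
print(f"mean spots / control subject: {results['profile']['mean_spots_control']:.0f}")
```

Typical output for this small 6-subject configuration:

```
chunk spot accuracy (voted): 91.2%
segment accuracy (voted):    89.8%
micro AUROC:                 0.995
mean spots / control subject: 3742
```

i.e. on held-out synthetic subjects, ~91% of the ~3,700 centerline spots
per subject receive the correct one-of-20 chunk label after voting, and
~90% of the junction-to-junction segments carry the right chunk; the
one-vs-rest ROC area of the spot-to-chunk classifier is near-perfect.
(Accuracy at the documented 30-subject scale is a few points higher —
small cohorts leave only 2 test subjects.)

The same stages are scriptable from the shell:

```bash
arterylabel simulate --cohort control --n 3 --seed 7 --spacing 0.284 --out sim/
arterylabel extract  --in sim/control-00007_vessels.nii.gz --prune-mm 2.0 --out ext/
arterylabel features --in sim/control-00007_vessels.nii.gz \
                     --centerlines ext/centerlines.json --out spots.csv
arterylabel run-all  --seed 1 --n-control 30 --n-icas 8 --out experiment/
```

## Layout

```
src/arterylabel/
  volume.py      VoxelVolume / LabelVolume containers, NIfTI I/O
  synthetic.py   tree template, cohort sampling, pathology, voxelisation
  geometry.py    resampling, surface, skeleton graph, pruning, centerlines
  features.py    spot sampling, cross-sections, the 9-feature vectors
  hierarchy.py   62-branch / 20-chunk nomenclature, segments, ground truth
  classify.py    splits, chunk/branch MLPs, voting, post-processing
  evaluate.py    metrics, ROC/PR, groupwise statistics, separability
  pipeline.py    end-to-end orchestration, caching, seeding
  cli.py         command-line interface
  data/nomenclature.json   the editable 62-branch nomenclature resource
```
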