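# tractconc

Concordance analysis between white-matter tract segmentations, their
voxelwise uncertainty, and navigated-stimulation motor-response masks.

The package implements a complete evaluation pipeline:

1. **Response masks** (`tractconc.ntms`) — classify exported motor
   responses into three classes by amplitude (positive at >= 50 µV),
   latency (inclusive 18–26 ms window) and primary-motor-cortex
   membership (`+M1+`, `-M1+`, `-M1-`), rasterize them onto a 1 mm³ grid,
   and filter against intracranial and white-matter masks.
2. **Ensemble aggregation** (`tractconc.ensemble`) — combine T stochastic
   segmentation probability maps into a mean map, a binary tract mask
   (strict threshold at 0.5) and a voxelwise uncertainty map
   (across-member std, or binary entropy of the mean).
3. **Concordance** (`tractconc.concordance`) — overlap coefficient
   (|A∩B| / min(|A|,|B|)) and Dice per subject/class/method, cohort
   aggregation, and the paired Wilcoxon signed-rank method comparison.
4. **Uncertainty vs distance** (`tractconc.uncdist`) — Euclidean distance
   transform (mm, anisotropy-aware), per-response-voxel
   (uncertainty, distance) pairs, a 30-bin joint histogram with per-bin
   mean/std, Spearman rank correlation and an OLS linear trend.
5. **Synthetic phantoms** (`tractconc.synthetic`) — fully seeded phantom
   cohorts (tubular tract, boundary-concentrated ensemble variability,
   three distance-ordered response classes) so the whole pipeline runs
   and is validated without clinical data.
6. **Pipeline + CLI** (`tractconc.pipeline`, `tractconc.cli`) —
   per-subject orchestration with failure isolation, deterministic
   CSV/JSON reports, and a cohort characteristics summary.

## CLI

```bash
# generate a seeded 16-subject phantom cohort
tractconc simulate --n-subjects 16 --seed 7 --out-dir scratch/cohort

# run every stage and write concordance.csv, histogram.csv, summary.json
tractconc run --data-dir scratch/cohort --out-dir scratch/results

# individual stages
tractconc process-ntms scratch/cohort/sub-01
tractconc aggregate-ensemble scratch/cohort/sub-01
tractconc report --cohort-csv scratch/cohort/cohort.csv
```

Expected subject layout: `responses.csv`,
`{m1,wm,intracranial}.nii.gz`, `ensemble/*.nii.gz` (one probability map
per stochastic pass), optional `alt_mask.nii.gz` for a second method.
All thresholds (`--amp-threshold`, `--latency-window`, `--binarize-tau`,
`--n-bins`, `--uncertainty-estimator`, …) are configurable; every run
records its full configuration, a config hash and the overlap-coefficient
definition in `summary.json`.

## Notes

* The overlap coefficient is intersection-over-minimum
  (Szymkiewicz–Simpson): 1 when the smaller mask is enclosed by the
  larger, 0 when disjoint.
* Binarization is strict (`p > τ`); a voxel exactly at the threshold is
  background.
* Wilcoxon signed-rank drops zero differences; the exact null is used for
  n ≤ 25 without ties, otherwise the tie-corrected normal approximation.
* Undefined metrics (empty masks) are reported as NA, never as 0.
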