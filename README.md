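# nodeval

Nodule-level evaluation of lesion-detection CAD systems for chest CT, built
around the methodology used to validate nodule detectors against a
multi-reader reference standard with known malignancy status.

Evaluating a nodule CAD system on clinical scans poses three linked
problems. First, there is no single ground truth: substantial interobserver
variability means the reference must be assembled from several radiologists'
independent annotations. Second, many marks are indeterminate (sub-3-mm
micronodules, masses over 30 mm, findings only a minority of readers saw),
and penalising or crediting detections on them would distort the comparison.
Third, comparing the CAD with an individual reader is only fair if that
reader is never scored against their own marks and if the CAD is pinned to a
comparable operating point. `nodeval` implements this whole evaluation
stack, together with a synthetic-cohort generator that emulates the study
structure so every component can be exercised end to end without clinical
data.

## What it computes

* **Consensus reference standard** — per-reader marks are clustered per scan
  (a pair merges when the centre distance is within the larger equivalent
  radius); clusters marked by at least 3 of 5 readers with an averaged
  volume-equivalent diameter *d* = (6V/π)^(1/3) in [3, 30] mm become
  reference nodules with averaged measurements; everything else goes to an
  exclusion list. A cancer-registry table relabels nodules as primary
  cancer / metastasis and adds panel-missed cancers to the reference.
* **Matching** — the standard hit criterion: a detection hits a nodule when
  its centre lies within the nodule radius (boundary inclusive). Detections
  on exclusion-list findings are ignored; extra hits on an already-detected
  nodule are duplicates, not false positives.
* **FROC / CPM** — sensitivity at the seven predefined rates 0.125, 0.25,
  0.5, 1, 2, 4, 8 FP/scan; the CPM is their mean. 95% confidence intervals
  by scan-level bootstrap (1,000 replicates). Threshold calibration picks
  the largest operating point with FP/scan at or below a target (1 FP/scan
  by default).
* **Reader-vs-AI comparison** — each reader is scored against a
  leave-one-out reference rebuilt from the other four readers; the AI is
  recalibrated to 1 FP/scan on the same reference, and the per-nodule
  detection vectors are compared with a two-sided paired permutation test
  (1,000 iterations, add-one correction).

## Worked example

```python
import nodeval as nv

cohort = nv.generate_cohort(nv.CohortConfig(seed=7))          # 100 scans
annotations = nv.simulate_readers(cohort, nv.default_reader_panel())
predictions = nv.simulate_cad(cohort, nv.CADProfile.calibrated(0.9))

ref = nv.build_reference_standard(annotations, cohort.scans)
ref, missed = nv.link_malignancy(ref, cohort.registry())

view = nv.select_subset(ref, nv.SubsetSpec(min_diameter=3.0))
match = nv.match_predictions(predictions, view)
curve = nv.froc_curve(match)
threshold, point = nv.calibrate_threshold(curve, target_fp_per_scan=1.0)
ci = nv.bootstrap_ci(predictions, view, n_boot=1000, seed=7)

res = nv.compare_ai_vs_reader(predictions, "r2", annotations, cohort.scans,
                              cohort.registry(),
                              nv.SubsetSpec(3.0, "metastasis"), seed=7)
```

which prints, with the formatting used in the example script:

```
210 reference nodules, 314 indeterminate findings, 22 panel-missed cancers
sensitivity at 1 FP/s: 90.5% (threshold 0.166)
CPM: 90.5% (95% CI 85.2-95.0%)
reader r2 (metastases): 32% at 0.15 FP/s; AI recalibrated: 95% at 1.00 FP/s; p = 0.001
```

Reading: clustering the five simulated readers' marks and applying the
majority vote and 3–30 mm size gate leaves 210 reference nodules and 314
indeterminate findings (detections on the latter are ignored during scoring,
not counted as false positives); 22 registry cancers were missed by the
panel majority and are nevertheless targets, so the AI can outscore the
panel. The CAD profile was configured
to detect 90% of nodules at its 1-FP/scan operating point and the pipeline
reports 90.5% — the closed loop recovers the configured value. The weakest
simulated reader finds 32% of metastases; the AI, recalibrated to 1 FP/scan
on that reader's leave-one-out reference, finds 95%, and the paired
permutation test calls the difference significant.

## Command line

```sh
nodeval simulate  --out run --seed 7          # synthetic cohort CSVs
nodeval consensus -c cfg.yaml                 # reference + exclusion list
nodeval evaluate  -c cfg.yaml                 # per-subset sensitivity table
nodeval compare   -c cfg.yaml                 # reader-vs-AI comparison table
```

All inputs and outputs are plain CSV in a LUNA16-style dialect (scan id plus
world-mm coordinates); see the `nodeval.io` docstrings for the exact
columns. `evaluate` writes `table3.csv` (one row per nodule subset, one
column per FP rate plus CPM with CIs), per-subset FROC point files, and a
JSON run log with the seed, config hash, and cluster-conservation counts.
`compare` writes `comparison.csv` (reader and recalibrated-AI operating
points with p-values) and per-category average FROC curves.

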