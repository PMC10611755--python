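# Methods

This note documents the statistical procedures implemented in `nodeval`,
the modelling assumptions behind the synthetic-cohort generator, and the
numerical choices made where the underlying methodology leaves room.

## Consensus reference standard

Five readers independently mark nodules; the reference is built in three
steps.

**Clustering.** Within one scan, marks from different readers are grouped by
greedy agglomerative merging: all cross-reader pairs are sorted by ascending
centre distance and a pair merges its clusters iff the distance is at most
the larger of the two equivalent radii and the clusters share no reader.
This reuses the evaluation's own hit-criterion geometry, is symmetric in the
readers, and is deterministic under any input order (ties are broken by a
total order on reader id and coordinates). An exhaustive-partition oracle in
the test suite confirms that on well-separated scenes the greedy result is
the optimal grouping. The method deliberately never merges two marks by the
same reader; a reader double-marking one lesion therefore produces a
spurious singleton, which ends up on the exclusion list as a minority
finding — the same effect a duplicated human mark would have.

**Gating.** Per cluster, centre, volume, and equivalent diameter are
averaged over contributing readers (volume and diameter are averaged
independently, matching how multi-reader measurement tables are reported;
the averaged pair is therefore not exactly sphere-consistent, and the
nodule radius used for matching is the averaged diameter over two). The
3–30 mm size gate applies to the averaged diameter. Size-valid clusters
below the 3-of-5 majority become `minority` exclusions; the nodule type is
the plurality vote with ties broken by the fixed priority solid >
part-solid > non-solid > perifissural > calcified.

**Registry linkage.** Each cancer-registry record is resolved in three
stages: (1) it relabels the nearest included nodule whose radius covers it;
(2) failing that, it promotes the nearest covering minority cluster to an
included nodule, keeping the averaged reader measurements; (3) failing
that, the record itself is appended as a target using the registry
localisation. Stages 2–3 constitute the panel-missed cancer report. Stage 2
matters: cancers seen by only one or two readers must still be reference
targets (that is precisely how a CAD system can outscore the panel), and
promoting the cluster preserves better measurements than the bare registry
point. Leave-one-out references are built by rebuilding the consensus from
the remaining four readers (majority threshold kept at 3, i.e. 3-of-4,
preserving "majority") and re-running the registry linkage, which retains
every registry-linked malignancy regardless of remaining agreement — only
the benign part of the reference varies per reader.

## Matching and subsets

A detection hits a nodule when its centre lies within the nodule's radius
(boundary inclusive; the inclusive reading avoids knife-edge float
behaviour at zero margin). A detection inside several targets is assigned
to the nearest centre (ties: lexicographically smaller nodule id); inside
both a target and an ignore region it goes to the target, favouring
sensitivity accounting. Among several hits on one nodule the highest score
is the true positive and the rest are duplicates, excluded from the FP
count. Subset analyses (minimum diameter 3/4/5 mm; actionable-benign,
primary-cancer, metastasis classes) keep the scan set fixed and turn
out-of-subset included nodules into ignore regions, so the FP/scan axis is
identical across subset rows.

## FROC statistics

The curve has one operating point per distinct detection score, anchored at
(0 FP/scan, 0 sensitivity). Sensitivity at a queried FP rate interpolates
linearly between operating points; beyond the largest achieved FP rate the
final sensitivity is carried forward (a conservative system is not
penalised at the 8 FP/scan query), and the CPM is the mean over the seven
predefined rates. Threshold calibration returns the smallest threshold
whose FP/scan does not exceed the target — the largest admissible operating
point; tables report both the achieved-point sensitivity and the
rate-interpolated sensitivity, since published "sensitivity at 1 FP/s"
values do not distinguish the two.

Confidence intervals are percentile (2.5/97.5) scan-level bootstrap: each
replicate resamples scan ids with replacement, a scan drawn k times
contributing its targets and false positives k times, and the full curve
plus interpolation is recomputed per replicate. Replicates with zero
targets are redrawn with a logged counter. Internally replicates are
evaluated on the pooled threshold grid with per-scan multiplicity weights —
exact, because extra thresholds land on the same step functions — which
keeps 1,000 replicates around 0.1 s on a 100-scan cohort.

The paired permutation test compares two binary detection vectors over the
same target nodules with the difference in detection fractions as statistic
and independent pair swaps (sign flips of per-nodule differences) as the
null. The p-value uses the add-one correction (1 + #{|T_perm| >= |T_obs|})
/ (1 + n_iter), so p is always positive; agreement with full 2^n
enumeration is property-tested. Percentages print half-up to one decimal;
p-values to three decimals with a "<0.001" floor.

## Synthetic cohort generator

The generator's defaults encode the study conditions: 25 scans in each of
the four categories (stage I cancer, metastases, actionable benign,
normal); a median of 2 nodules per scan (IQR 1–4); lognormal nodule
diameters with median 6.6 mm and IQR 4.7–11.9 mm; a type mixture of
81.5 / 6.3 / 3.3 / 5.6 / 3.3 % for solid / part-solid / non-solid /
perifissural / calcified; at most 15 metastases per scan. Primary cancers
draw from a larger lognormal (median 18 mm, capped at 30 mm so they remain
nodules rather than masses); metastases from a median-7-mm lognormal and a
median-4-per-scan count distribution, reflecting that metastases are
smaller and more numerous. Lognormals are parameterised by median and IQR
with sigma solved from the quartile ratio via the 0.6745 quantile relation;
since a lognormal's quartiles are geometrically symmetric about the median,
the stated (asymmetric) quartile pair is matched in median and ratio, not
in each quartile individually. Category rules are deterministic: metastasis
scans carry only metastases, stage-I scans exactly one primary cancer,
normal scans only sub-5-mm benign nodules.

Nodules are placed uniformly in a 280 x 280 x 240 mm scene with rejection
sampling enforcing pairwise centre separation of at least 1.5 x the radius
sum, so cluster and match assignments have a unique correct answer.
Consequently the generator does not emulate attached, juxtapleural, or
juxtavascular lesions, overlapping nodules, scanner effects, or anatomy of
any kind — passing closed-loop tests demonstrates correctness of the
evaluation machinery under unambiguous geometry, not CAD performance on
real scans.

Readers detect each nodule independently with probability
logistic(a + b·ln d) times a per-type multiplier, mark it with isotropic
Gaussian jitter (sd = 0.2 x radius by default, split across axes) and 10%
relative size noise, and add Poisson false-positive marks (default panel:
0.1–0.8 per scan, detection intercepts spanning roughly 30–90% sensitivity
at metastasis sizes, bracketing the heterogeneity of a real panel). The CAD
emits a candidate per nodule with a configurable probability, scored by a
logistic model in log-diameter with Gaussian noise, plus Poisson false
positives with Beta-distributed scores. `CADProfile.calibrated(s)`
constructs a profile whose sensitivity at 1 FP/scan equals `s` by
construction: candidate scores live in [0.6, 1] while FP scores follow
Beta(1, 8), so the threshold achieving 1 FP/scan sits far below every
candidate score and the detection rate at that operating point is exactly
the emission rate. This gives the closed-loop recovery tests a configured
truth that does not depend on tuning.

All simulation stages derive their generators from one global seed through
fixed per-stage offsets, so cohort, readers, and CAD streams can be
regenerated independently and every pipeline output is a pure function of
(inputs, seed).

## Problem sizes in the test suite

The suite favours deterministic oracles (exhaustive partition enumeration,
2^n permutation enumeration, brute-force matching) at small n, plus
moderate-size stochastic checks chosen to keep the full run near ten
seconds: bootstrap coverage uses 100 outer cohorts of 200 scans at 200
replicates; closed-loop sensitivity recovery uses a 200-scan cohort
(~500 nodules); the reader-vs-AI power check uses 50 repeats on a 40-scan
metastasis-only cohort (~180 targets) with 300 permutation iterations.

## Known limitations

* Matching is point-in-sphere only; no segmentation overlap (IoU/Dice)
  criteria, and no voxel-space handling — all geometry is world-mm points.
* The consensus has no second reading round or arbitration; discordant
  marks are resolved purely by the majority vote.
* Benign status is an input label; no follow-up stability logic is
  modelled.
* The bootstrap CI is percentile-based; no BCa or studentised variants.
* The synthetic readers' detection model is logistic in log-diameter only;
  real reader misses correlate with location and attachment, which the
  generator cannot reproduce.
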