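"""Standalone reader-vs-AI comparison with leave-one-out references.

Each panel reader is scored against a reference rebuilt from the other
readers (so nobody confirms their own marks); the AI is matched against the
same leave-one-out view and recalibrated to the target FP/s for each
comparison; significance is assessed with a two-sided paired permutation
test on the per-nodule detection vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import (
    ReferenceStandard,
    SubsetSpec,
    SubsetView,
    leave_one_out_reference,
    select_subset,
)
from .froc import (
    FROCCurve,
    calibrate_threshold,
    froc_curve,
    paired_permutation_test,
    sensitivity_at,
)
from .io import Annotation, Prediction, RegistryRecord, ScanRecord
from .matching import match_predictions, match_reader

__all__ = ["ReaderPoint", "ComparisonResult", "reader_performance",
           "compare_ai_vs_reader", "comparison_table"]

DEFAULT_CATEGORIES = ("actionable_benign", "primary_cancer", "metastasis")


@dataclass
class ReaderPoint:
    """A reader's operating point on one nodule category."""

    reader_id: str
    category: str
    sensitivity: float           # fraction
    sensitivity_ci: tuple[float, float]
    fp_per_scan: float
    fp_ci: tuple[float, float]
    n_targets: int
    n_detected: int


@dataclass
class ComparisonResult:
    reader_id: str
    category: str
    reader: ReaderPoint
    ai_threshold: float
    ai_sensitivity: float        # fraction, at the calibrated threshold
    ai_sensitivity_ci: tuple[float, float]
    ai_sensitivity_interpolated: float  # fraction, rate-interpolated
    ai_fp_per_scan: float
    ai_fp_ci: tuple[float, float]
    p_value: float
    significant: bool
    n_targets: int
    ai_curve: FROCCurve | None = None


def _scan_bootstrap(det: np.ndarray, tgt: np.ndarray, fp: np.ndarray,
                    n_boot: int, seed: int):
    """Percentile CIs for (sum det / sum tgt, sum fp / n) over scan resamples."""
    n = len(tgt)
    rng = np.random.default_rng(seed)
    sens = np.empty(n_boot)
    fps = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            t = tgt[idx].sum()
            if t > 0:
                break
        sens[b] = det[idx].sum() / t
        fps[b] = fp[idx].sum() / n
    s_lo, s_hi = np.percentile(sens, [2.5, 97.5])
    f_lo, f_hi = np.percentile(fps, [2.5, 97.5])
    return (float(s_lo), float(s_hi)), (float(f_lo), float(f_hi))


def _per_scan_counts(view: SubsetView, detected: Mapping[str, bool],
                     fp_by_scan: Mapping[str, int]):
    scan_ids = [s.scan_id for s in view.scans]
    index = {sid: i for i, sid in enumerate(scan_ids)}
    det = np.zeros(len(scan_ids))
    tgt = np.zeros(len(scan_ids))
    fp = np.zeros(len(scan_ids))
    for n in view.targets:
        i = index[n.scan_id]
        tgt[i] += 1
        if detected[n.nodule_id]:
            det[i] += 1
    for sid, k in fp_by_scan.items():
        fp[index[sid]] += k
    return det, tgt, fp


def _loo_view(annotations, manifest, registry, reader_id, spec,
              min_agreement, size_bounds, shared_reference=None):
    if shared_reference is not None:
        ref = shared_reference
    else:
        ref = leave_one_out_reference(annotations, manifest, registry,
                                      reader_id, min_agreement, size_bounds)
    return ref, select_subset(ref, spec)


def reader_performance(
    reader_id: str,
    annotations: Mapping[str, Sequence[Annotation]],
    manifest: Sequence[ScanRecord],
    registry: Sequence[RegistryRecord],
    spec: SubsetSpec,
    min_agreement: int = 3,
    size_bounds: tuple[float, float] = (3.0, 30.0),
    n_boot: int = 1000,
    seed: int = 0,
    shared_reference: ReferenceStandard | None = None,
) -> ReaderPoint:
    """Sensitivity and FP/s of one reader against the leave-one-out reference.

    ``shared_reference`` overrides the leave-one-out rebuild (debug use:
    forcing one common reference makes the AI side identical across readers).
    """
    if reader_id not in annotations:
        raise KeyError(f"unknown reader {reader_id!r}")
    _, view = _loo_view(annotations, manifest, registry, reader_id, spec,
                        min_agreement, size_bounds, shared_reference)
    rm = match_reader(annotations[reader_id], view)
    fp_by_scan: dict[str, int] = {}
    # recount FPs per scan for the bootstrap
    from .matching import _assign
    for a in annotations[reader_id]:
        hit, _ = _assign(a.center, a.scan_id, view)
        if hit is None:
            fp_by_scan[a.scan_id] = fp_by_scan.get(a.scan_id, 0) + 1
    det, tgt, fp = _per_scan_counts(view, rm.detected, fp_by_scan)
    (s_lo, s_hi), (f_lo, f_hi) = _scan_bootstrap(det, tgt, fp, n_boot, seed)
    return ReaderPoint(reader_id, spec.class_filter, rm.sensitivity,
                       (s_lo, s_hi), rm.fp_per_scan, (f_lo, f_hi),
                       rm.n_targets, rm.n_detected)


def compare_ai_vs_reader(
    predictions: Sequence[Prediction],
    reader_id: str,
    annotations: Mapping[str, Sequence[Annotation]],
    manifest: Sequence[ScanRecord],
    registry: Sequence[RegistryRecord],
    spec: SubsetSpec,
    target_fp: float = 1.0,
    min_agreement: int = 3,
    size_bounds: tuple[float, float] = (3.0, 30.0),
    n_boot: int = 1000,
    n_iter: int = 1000,
    seed: int = 0,
    shared_reference: ReferenceStandard | None = None,
) -> ComparisonResult:
    """Compare the AI, recalibrated to ``target_fp``, with one reader.

    The AI is matched against the reader's leave-one-out subset view; the
    detection threshold is recalibrated on that view so the achieved FP/s
    does not exceed ``target_fp``; the per-nodule binary detection vectors of
    AI-at-threshold and reader feed the paired permutation test (panel-missed
    registry nodules included).  Significance at p < 0.05.
    """
    reader = reader_performance(reader_id, annotations, manifest, registry,
                                spec, min_agreement, size_bounds, n_boot,
                                seed, shared_reference)
    _, view = _loo_view(annotations, manifest, registry, reader_id, spec,
                        min_agreement, size_bounds, shared_reference)
    match = match_predictions(predictions, view)
    curve = froc_curve(match)
    threshold, achieved = calibrate_threshold(curve, target_fp)
    sens_interp = float(sensitivity_at(curve, [target_fp])[0])

    order = match.target_ids
    ai_vec = np.array(
        [match.best_score[nid] is not None and match.best_score[nid] >= threshold
         for nid in order], dtype=float)
    rm = match_reader(annotations[reader_id], view)
    reader_vec = np.array([rm.detected[nid] for nid in order], dtype=float)
    perm = paired_permutation_test(ai_vec, reader_vec, n_iter=n_iter,
                                   seed=seed + 1)

    # scan-level bootstrap of the AI operating point at the fixed threshold
    fp_by_scan: dict[str, int] = {}
    for r in match.records:
        if r.label == "FP" and r.prediction.score >= threshold:
            sid = r.prediction.scan_id
            fp_by_scan[sid] = fp_by_scan.get(sid, 0) + 1
    detected = {nid: bool(ai_vec[i]) for i, nid in enumerate(order)}
    det, tgt, fp = _per_scan_counts(view, detected, fp_by_scan)
    (s_lo, s_hi), (f_lo, f_hi) = _scan_bootstrap(det, tgt, fp, n_boot,
                                                 seed + 2)
    return ComparisonResult(
        reader_id, spec.class_filter, reader, threshold,
        float(ai_vec.mean()) if len(ai_vec) else float("nan"),
        (s_lo, s_hi), sens_interp, achieved.fp_per_scan, (f_lo, f_hi),
        perm.p_value, perm.p_value < 0.05, len(order), curve)


def comparison_table(
    predictions: Sequence[Prediction],
    annotations: Mapping[str, Sequence[Annotation]],
    manifest: Sequence[ScanRecord],
    registry: Sequence[RegistryRecord],
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    target_fp: float = 1.0,
    min_agreement: int = 3,
    size_bounds: tuple[float, float] = (3.0, 30.0),
    n_boot: int = 1000,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """One row per (reader, category), mirroring the published table layout."""
    rows = []
    results = []
    ss = np.random.SeedSequence(seed)
    for reader_id in sorted(annotations):
        for category in categories:
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = compare_ai_vs_reader(
                predictions, reader_id, annotations, manifest, registry,
                SubsetSpec(3.0, category), target_fp, min_agreement,
                size_bounds, n_boot, n_iter, sub_seed)
            results.append(res)
            rows.append({
                "reader": reader_id,
                "category": category,
                "fp_per_scan": res.reader.fp_per_scan,
                "fp_ci_lo": res.reader.fp_ci[0],
                "fp_ci_hi": res.reader.fp_ci[1],
                "sensitivity": 100 * res.reader.sensitivity,
                "sens_ci_lo": 100 * res.reader.sensitivity_ci[0],
                "sens_ci_hi": 100 * res.reader.sensitivity_ci[1],
                "ai_fp_per_scan": res.ai_fp_per_scan,
                "ai_fp_ci_lo": res.ai_fp_ci[0],
                "ai_fp_ci_hi": res.ai_fp_ci[1],
                "ai_sensitivity": 100 * res.ai_sensitivity,
                "ai_ci_lo": 100 * res.ai_sensitivity_ci[0],
                "ai_ci_hi": 100 * res.ai_sensitivity_ci[1],
                "p_value": res.p_value,
                "n_targets": res.n_targets,
            })
    return pd.DataFrame(rows), results
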