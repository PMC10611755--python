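"""Point-in-sphere matching of detections against a reference subset view.

The hit criterion is the field's standard one for nodule CAD evaluation: a
detection hits a reference nodule when its centre lies within the nodule's
radius of the nodule centre (boundary inclusive).  Detections that hit only
exclusion-list findings (or out-of-subset nodules) are ignored; among several
detections hitting the same nodule only the highest-scoring one is the true
positive, the rest are duplicates and excluded from the FP count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import SubsetView
from .io import Annotation, Prediction

__all__ = ["PredictionMatch", "MatchResult", "ReaderMatchResult",
           "match_predictions", "match_reader", "export_match_table"]

logger = logging.getLogger(__name__)

LABELS = ("TP", "FP", "ignored", "duplicate")


@dataclass
class PredictionMatch:
    """Per-prediction outcome of matching."""

    prediction: Prediction
    label: str
    nodule_id: str | None = None
    distance: float = math.nan


@dataclass
class MatchResult:
    """All per-prediction labels plus per-target best scores for one view."""

    records: list[PredictionMatch]
    target_ids: list[str]
    best_score: dict[str, float | None]
    n_scans: int

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in LABELS}
        for r in self.records:
            out[r.label] += 1
        return out

    @property
    def tp_scores(self) -> np.ndarray:
        return np.array([s for s in self.best_score.values() if s is not None],
                        dtype=float)

    @property
    def fp_scores(self) -> np.ndarray:
        return np.array([r.prediction.score for r in self.records
                         if r.label == "FP"], dtype=float)


@dataclass
class ReaderMatchResult:
    """Matching outcome for one reader's (unscored) annotations."""

    detected: dict[str, bool]
    fp_count: int
    n_scans: int

    @property
    def n_targets(self) -> int:
        return len(self.detected)

    @property
    def n_detected(self) -> int:
        return sum(self.detected.values())

    @property
    def sensitivity(self) -> float:
        if not self.detected:
            raise ValueError("no target nodules in view")
        return self.n_detected / len(self.detected)

    @property
    def fp_per_scan(self) -> float:
        return self.fp_count / self.n_scans


def _assign(center: np.ndarray, scan_id: str, view: SubsetView):
    """Resolve one mark: (nodule, distance) hit, 'ignored', or None (miss).

    A mark inside several targets goes to the nearest centre (ties: smaller
    nodule_id); a mark inside both a target and an ignore region goes to the
    target.
    """
    hits = []
    for n in view.targets:
        if n.scan_id != scan_id:
            continue
        d = float(np.linalg.norm(center - n.center))
        if d <= n.radius:
            hits.append((d, n.nodule_id, n))
    if hits:
        hits.sort(key=lambda h: (h[0], h[1]))
        d, _, nod = hits[0]
        return nod, d
    for region in view.ignore:
        if region.scan_id != scan_id:
            continue
        if float(np.linalg.norm(center - np.asarray(region.center))) <= region.radius:
            return "ignored", math.nan
    return None, math.nan


def match_predictions(predictions: Sequence[Prediction],
                      view: SubsetView) -> MatchResult:
    """Label every prediction TP/FP/ignored/duplicate against the view."""
    scan_ids = view.scan_ids
    records: list[PredictionMatch] = []
    per_nodule: dict[str, list[int]] = {}
    for idx, p in enumerate(predictions):
        if p.scan_id not in scan_ids:
            raise ValueError(f"prediction on unknown scan {p.scan_id!r}")
        hit, d = _assign(p.center, p.scan_id, view)
        if hit is None:
            records.append(PredictionMatch(p, "FP"))
        elif hit == "ignored":
            records.append(PredictionMatch(p, "ignored"))
        else:
            records.append(PredictionMatch(p, "TP", hit.nodule_id, d))
            per_nodule.setdefault(hit.nodule_id, []).append(idx)
    best_score: dict[str, float | None] = {n.nodule_id: None
                                           for n in view.targets}
    for nodule_id, idxs in per_nodule.items():
        # highest score wins; ties broken by distance then input order
        idxs.sort(key=lambda i: (-records[i].prediction.score,
                                 records[i].distance, i))
        best_score[nodule_id] = records[idxs[0]].prediction.score
        for i in idxs[1:]:
            records[i].label = "duplicate"
    return MatchResult(records, [n.nodule_id for n in view.targets],
                       best_score, view.n_scans)


def match_reader(annotations: Sequence[Annotation],
                 view: SubsetView) -> ReaderMatchResult:
    """Score one reader's marks with the same hit geometry.

    Marks hitting ignore regions do not count as FP; several marks by the
    same reader on one nodule collapse to a single detection.
    """
    scan_ids = view.scan_ids
    detected: dict[str, bool] = {n.nodule_id: False for n in view.targets}
    fp = 0
    seen: set[str] = set()
    for a in annotations:
        if a.scan_id not in scan_ids:
            raise ValueError(f"annotation on unknown scan {a.scan_id!r}")
        hit, _ = _assign(a.center, a.scan_id, view)
        if hit is None:
            fp += 1
        elif hit != "ignored":
            if hit.nodule_id in seen:
                logger.warning("reader %s double-marked nodule %s; extra mark "
                               "discarded", a.reader_id, hit.nodule_id)
            else:
                seen.add(hit.nodule_id)
                detected[hit.nodule_id] = True
    return ReaderMatchResult(detected, fp, view.n_scans)


def export_match_table(match: MatchResult, path) -> None:
    """Write one row per prediction: scan, score, label, match, distance."""
    import pandas as pd

    rows = [
        {"scan_id": r.prediction.scan_id,
         "score": round(r.prediction.score, 6),
         "label": r.label,
         "matched_nodule_id": r.nodule_id or "",
         "distance_mm": "" if math.isnan(r.distance) else round(r.distance, 4)}
        for r in match.records
    ]
    cols = ["scan_id", "score", "label", "matched_nodule_id", "distance_mm"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
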