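"""Majority-vote consensus reference standard with exclusion list.

Five readers independently mark nodules on each scan.  Marks from different
readers are grouped into clusters (one physical lesion each); a cluster whose
averaged equivalent diameter lies in the 3-30 mm gate and that was marked by
at least ``min_agreement`` readers becomes an included reference nodule with
averaged measurements.  Everything else goes to an exclusion list of
indeterminate findings: detections matching those are later ignored (neither
true nor false positive).

Malignancy is attached afterwards from a cancer-registry table: a registry
record claims the nearest nodule whose radius covers it; cancers the panel
majority missed are still added to the reference (the registry readers
localised every registered cancer), so AI sensitivity can exceed panel
sensitivity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import (
    Annotation,
    NODULE_TYPES,
    RegistryRecord,
    ScanRecord,
    sphere_volume,
)

__all__ = [
    "ReferenceNodule",
    "ExcludedFinding",
    "ReferenceStandard",
    "SubsetSpec",
    "SubsetView",
    "IgnoreRegion",
    "cluster_annotations",
    "build_reference_standard",
    "link_malignancy",
    "select_subset",
    "leave_one_out_reference",
]

#: Priority used to break ties in the per-cluster nodule-type plurality vote.
_TYPE_PRIORITY = {t: i for i, t in enumerate(NODULE_TYPES)}

CLASS_FILTERS = ("all", "actionable_benign", "primary_cancer", "metastasis")


@dataclass(eq=False)
class ReferenceNodule:
    """A consensus nodule: measurements averaged over contributing readers."""

    nodule_id: str
    scan_id: str
    center: np.ndarray
    volume: float
    equivalent_diameter: float
    nodule_type: str
    agreement: int
    malignancy: str = "benign"
    actionable: bool = False
    detected_by_panel: bool = True

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    @property
    def radius(self) -> float:
        return self.equivalent_diameter / 2.0


@dataclass(eq=False)
class ExcludedFinding:
    """An indeterminate finding: fails the size gate or the majority vote."""

    scan_id: str
    center: np.ndarray
    equivalent_diameter: float
    agreement: int
    reason: str  # too_small | too_large | minority
    volume: float = 0.0
    nodule_type: str = "solid"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.volume <= 0.0:
            self.volume = sphere_volume(self.equivalent_diameter)

    @property
    def radius(self) -> float:
        return self.equivalent_diameter / 2.0


@dataclass
class ReferenceStandard:
    scans: list[ScanRecord]
    nodules: list[ReferenceNodule]
    exclusion_list: list[ExcludedFinding]
    min_agreement: int
    n_readers: int

    def nodule(self, nodule_id: str) -> ReferenceNodule:
        for n in self.nodules:
            if n.nodule_id == nodule_id:
                return n
        raise KeyError(nodule_id)


@dataclass(frozen=True)
class SubsetSpec:
    """Which nodules count as targets in one evaluation run."""

    min_diameter: float = 3.0
    class_filter: str = "all"

    def __post_init__(self) -> None:
        if self.min_diameter < 3.0:
            raise ValueError("min_diameter must be >= 3 mm")
        if self.class_filter not in CLASS_FILTERS:
            raise ValueError(f"class_filter must be one of {CLASS_FILTERS}")

    def admits(self, nodule: ReferenceNodule) -> bool:
        if nodule.equivalent_diameter < self.min_diameter:
            return False
        if self.class_filter == "all":
            return True
        if self.class_filter == "actionable_benign":
            return nodule.actionable
        return nodule.malignancy == self.class_filter


@dataclass(frozen=True)
class IgnoreRegion:
    """A sphere detections may fall into without being scored either way."""

    scan_id: str
    center: tuple[float, float, float]
    radius: float


@dataclass
class SubsetView:
    """Evaluation view: target nodules, ignore regions, and the scan set.

    The scan set is always the full manifest so that the FP/scan denominator
    is identical across subset analyses; included nodules outside the subset
    become ignore regions (detections on them are neither TP nor FP).
    """

    targets: list[ReferenceNodule]
    ignore: list[IgnoreRegion]
    scans: list[ScanRecord]

    @property
    def scan_ids(self) -> set[str]:
        return {s.scan_id for s in self.scans}

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _ann_key(a: Annotation):
    # deterministic total order on annotations within one scan
    return (a.reader_id, round(a.center[0], 9), round(a.center[1], 9),
            round(a.center[2], 9), a.equivalent_diameter)


def _mergeable(a: Annotation, b: Annotation) -> bool:
    return float(np.linalg.norm(a.center - b.center)) <= max(a.radius, b.radius)


def cluster_annotations(annotations: Sequence[Annotation]
                        ) -> list[list[Annotation]]:
    """Group one scan's multi-reader marks into per-lesion clusters.

    Greedy agglomerative merging over annotation pairs in ascending
    centre-distance order: a pair merges iff the distance is within the larger
    of the two radii (the same geometry as the evaluation hit criterion) and
    the two clusters share no reader.  Deterministic under any input order.
    """
    if not annotations:
        return []
    scan_ids = {a.scan_id for a in annotations}
    if len(scan_ids) != 1:
        raise ValueError(f"annotations span multiple scans: {sorted(scan_ids)}")

    anns = sorted(annotations, key=_ann_key)
    parent = list(range(len(anns)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    readers: list[set[str]] = [{a.reader_id} for a in anns]
    pairs = []
    for i, j in itertools.combinations(range(len(anns)), 2):
        a, b = anns[i], anns[j]
        if a.reader_id == b.reader_id:
            continue
        d = float(np.linalg.norm(a.center - b.center))
        if d <= max(a.radius, b.radius):
            pairs.append((d, i, j))
    pairs.sort()
    for _, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if readers[ri] & readers[rj]:
            continue
        parent[rj] = ri
        readers[ri] |= readers[rj]
    clusters: dict[int, list[Annotation]] = {}
    for i, a in enumerate(anns):
        clusters.setdefault(find(i), []).append(a)
    out = list(clusters.values())
    out.sort(key=lambda c: _ann_key(min(c, key=_ann_key)))
    return out


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _consensus_type(cluster: Sequence[Annotation]) -> str:
    counts: dict[str, int] = {}
    for a in cluster:
        counts[a.nodule_type] = counts.get(a.nodule_type, 0) + 1
    best = max(counts.values())
    tied = [t for t, c in counts.items() if c == best]
    return min(tied, key=_TYPE_PRIORITY.__getitem__)


def _is_actionable(nodule: ReferenceNodule) -> bool:
    return (
        nodule.malignancy == "benign"
        and nodule.equivalent_diameter >= 5.0
        and nodule.nodule_type not in ("calcified", "perifissural")
    )


def build_reference_standard(
    annotations: Mapping[str, Sequence[Annotation]],
    manifest: Sequence[ScanRecord],
    min_agreement: int = 3,
    size_bounds: tuple[float, float] = (3.0, 30.0),
) -> ReferenceStandard:
    """Cluster per-reader marks and apply the size gate and majority vote.

    Per cluster the consensus centre, volume and equivalent diameter are the
    means over the contributing readers; the size gate is applied to the
    averaged diameter.  Size-failing clusters are excluded as
    ``too_small``/``too_large``; size-valid clusters below ``min_agreement``
    as ``minority``.
    """
    n_readers = len(annotations)
    if min_agreement > n_readers:
        raise ValueError(
            f"min_agreement={min_agreement} exceeds the number of readers "
            f"({n_readers})"
        )
    lo, hi = size_bounds
    scan_ids = {s.scan_id for s in manifest}
    by_scan: dict[str, list[Annotation]] = {}
    for reader_id in sorted(annotations):
        for a in annotations[reader_id]:
            if a.scan_id not in scan_ids:
                raise ValueError(
                    f"annotation on scan {a.scan_id!r} absent from manifest"
                )
            by_scan.setdefault(a.scan_id, []).append(a)

    nodules: list[ReferenceNodule] = []
    excluded: list[ExcludedFinding] = []
    for scan in manifest:
        anns = by_scan.get(scan.scan_id, [])
        k = 0
        for cluster in cluster_annotations(anns):
            center = np.mean([a.center for a in cluster], axis=0)
            volume = float(np.mean([a.volume for a in cluster]))
            diameter = float(np.mean([a.equivalent_diameter for a in cluster]))
            ntype = _consensus_type(cluster)
            agreement = len({a.reader_id for a in cluster})
            if diameter < lo or diameter > hi:
                reason = "too_small" if diameter < lo else "too_large"
                excluded.append(ExcludedFinding(scan.scan_id, center, diameter,
                                                agreement, reason, volume, ntype))
            elif agreement < min_agreement:
                excluded.append(ExcludedFinding(scan.scan_id, center, diameter,
                                                agreement, "minority", volume,
                                                ntype))
            else:
                k += 1
                nod = ReferenceNodule(f"{scan.scan_id}_n{k:03d}", scan.scan_id,
                                      center, volume, diameter, ntype, agreement)
                nod.actionable = _is_actionable(nod)
                nodules.append(nod)
    return ReferenceStandard(list(manifest), nodules, excluded,
                             min_agreement, n_readers)


def link_malignancy(
    ref: ReferenceStandard,
    registry: Sequence[RegistryRecord],
) -> tuple[ReferenceStandard, list[dict]]:
    """Attach malignancy labels from the registry; add panel-missed cancers.

    Each registry record is resolved in three stages:

    1. linked to the nearest *included* nodule whose radius covers the record
       centre (hit criterion);
    2. else the nearest size-valid ``minority`` excluded cluster covering the
       record is promoted to an included nodule (its averaged reader
       measurements are kept; it leaves the exclusion list);
    3. else the record itself is appended as a new included nodule using the
       registry localisation and diameter.

    Stages 2-3 are cancers missed by the panel majority and are returned in
    the missed-cancer report (``detected_by_panel`` False).  All unlinked
    nodules remain benign; actionable flags are recomputed.
    """
    scan_ids = {s.scan_id for s in ref.scans}
    nodules = [replace(n) for n in ref.nodules]
    excluded = list(ref.exclusion_list)
    missed: list[dict] = []
    appended = 0
    for rec in registry:
        if rec.scan_id not in scan_ids:
            raise ValueError(
                f"registry record on scan {rec.scan_id!r} absent from manifest"
            )
        # stage 1: nearest included nodule covering the record
        best, best_d = None, np.inf
        for n in nodules:
            if n.scan_id != rec.scan_id:
                continue
            d = float(np.linalg.norm(n.center - rec.center))
            if d <= n.radius and d < best_d:
                best, best_d = n, d
        if best is not None:
            best.malignancy = rec.status
            continue
        # stage 2: promote a covering minority cluster
        bex, bex_d = None, np.inf
        for e in excluded:
            if e.scan_id != rec.scan_id or e.reason != "minority":
                continue
            d = float(np.linalg.norm(e.center - rec.center))
            if d <= e.radius and d < bex_d:
                bex, bex_d = e, d
        if bex is not None:
            excluded.remove(bex)
            appended += 1
            nod = ReferenceNodule(f"{rec.scan_id}_r{appended:03d}", rec.scan_id,
                                  bex.center, bex.volume,
                                  bex.equivalent_diameter, bex.nodule_type,
                                  bex.agreement, rec.status,
                                  detected_by_panel=False)
            nodules.append(nod)
            missed.append({"record": rec, "action": "promoted_minority",
                           "nodule_id": nod.nodule_id})
            continue
        # stage 3: append from the registry localisation
        appended += 1
        nod = ReferenceNodule(f"{rec.scan_id}_r{appended:03d}", rec.scan_id,
                              rec.center, sphere_volume(rec.diameter),
                              rec.diameter, "solid", 0, rec.status,
                              detected_by_panel=False)
        nodules.append(nod)
        missed.append({"record": rec, "action": "appended",
                       "nodule_id": nod.nodule_id})
    for n in nodules:
        n.actionable = _is_actionable(n)
    return (ReferenceStandard(ref.scans, nodules, excluded, ref.min_agreement,
                              ref.n_readers), missed)


def select_subset(ref: ReferenceStandard, spec: SubsetSpec) -> SubsetView:
    """Build the evaluation view for one subset analysis.

    Targets are the included nodules admitted by ``spec``; the ignore set is
    the exclusion list plus every included nodule outside the subset, so the
    FP/scan axis is shared across subsets.
    """
    targets = [n for n in ref.nodules if spec.admits(n)]
    ignore = [
        IgnoreRegion(e.scan_id, tuple(e.center), e.radius)
        for e in ref.exclusion_list
    ] + [
        IgnoreRegion(n.scan_id, tuple(n.center), n.radius)
        for n in ref.nodules if not spec.admits(n)
    ]
    return SubsetView(targets, ignore, list(ref.scans))


def leave_one_out_reference(
    annotations: Mapping[str, Sequence[Annotation]],
    manifest: Sequence[ScanRecord],
    registry: Sequence[RegistryRecord],
    excluded_reader: str,
    min_agreement: int = 3,
    size_bounds: tuple[float, float] = (3.0, 30.0),
) -> ReferenceStandard:
    """Reference rebuilt from the other readers, for scoring one reader.

    The benign consensus and exclusion list are rebuilt from the remaining
    ``n - 1`` readers with the majority threshold unchanged; re-running the
    registry linkage afterwards retains every registry-linked malignant nodule
    regardless of the remaining agreement.
    """
    if excluded_reader not in annotations:
        raise KeyError(f"unknown reader {excluded_reader!r}")
    remaining = {r: v for r, v in annotations.items() if r != excluded_reader}
    if len(remaining) < min_agreement:
        raise ValueError(
            f"only {len(remaining)} readers remain, fewer than "
            f"min_agreement={min_agreement}"
        )
    ref = build_reference_standard(remaining, manifest, min_agreement,
                                   size_bounds)
    ref, _ = link_malignancy(ref, registry)
    return ref
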