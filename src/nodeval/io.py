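"""Data model and CSV readers/writers for nodule evaluation inputs.

All geometry is in world coordinates (millimetres); a nodule is represented by
its centre and the diameter of the volume-equivalent sphere.  The CSV dialects
are LUNA16-style (scan id plus world-mm coordinates) extended with reader,
type, and malignancy columns:

* ``scans.csv``        — ``scan_id,category[,patient_id]``
* ``annotations.csv``  — ``scan_id,reader_id,coord_x_mm,coord_y_mm,coord_z_mm,
  volume_mm3,nodule_type[,lobe]`` (``diameter_mm`` may replace or accompany
  ``volume_mm3``; the missing one is derived from the sphere identity)
* ``predictions.csv``  — ``scan_id,coord_x_mm,coord_y_mm,coord_z_mm,score``
* ``registry.csv``     — ``scan_id,coord_x_mm,coord_y_mm,coord_z_mm,
  diameter_mm,status``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "NODULE_TYPES",
    "MALIGNANCIES",
    "ScanRecord",
    "Annotation",
    "Prediction",
    "RegistryRecord",
    "equivalent_diameter",
    "sphere_volume",
    "read_scan_manifest",
    "write_scan_manifest",
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
    "read_registry",
    "write_registry",
]

#: The four balanced scan categories of the study design.
CATEGORIES = ("stage1_cancer", "metastases", "actionable_benign", "normal")

#: Nodule types recorded by the reading panel.
NODULE_TYPES = ("solid", "part_solid", "non_solid", "perifissural", "calcified")

#: Malignancy statuses; ``benign`` is the default absence of a registry record.
MALIGNANCIES = ("benign", "primary_cancer", "metastasis")

_REGISTRY_STATUSES = ("primary_cancer", "metastasis")


def equivalent_diameter(volume: float) -> float:
    """Diameter (mm) of the sphere with the given volume (mm^3).

    ``d = (6 V / pi) ** (1/3)``; strictly increasing in ``volume``.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def sphere_volume(diameter: float) -> float:
    """Volume (mm^3) of a sphere with the given diameter (mm)."""
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    return math.pi / 6.0 * diameter**3


@dataclass
class ScanRecord:
    """One CT scan in the evaluation manifest (nodule-free scans included)."""

    scan_id: str
    category: str
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for scan {self.scan_id!r}"
            )


@dataclass(eq=False)
class Annotation:
    """A single reader's mark on a single scan."""

    scan_id: str
    reader_id: str
    center: np.ndarray
    volume: float
    equivalent_diameter: float
    nodule_type: str
    lobe: str | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector (world mm)")
        if self.volume <= 0 or self.equivalent_diameter <= 0:
            raise ValueError(
                f"non-positive size for annotation on scan {self.scan_id!r}"
            )
        expected = equivalent_diameter(self.volume)
        if not math.isclose(expected, self.equivalent_diameter, rel_tol=1e-6):
            raise ValueError(
                "volume and equivalent_diameter are inconsistent: "
                f"{self.volume} mm^3 implies {expected:.6f} mm, "
                f"got {self.equivalent_diameter} mm"
            )
        if self.nodule_type not in NODULE_TYPES:
            raise ValueError(f"unknown nodule_type {self.nodule_type!r}")

    @property
    def radius(self) -> float:
        return self.equivalent_diameter / 2.0

    @classmethod
    def from_volume(cls, scan_id, reader_id, center, volume, nodule_type,
                    lobe=None) -> "Annotation":
        return cls(scan_id, reader_id, center, volume,
                   equivalent_diameter(volume), nodule_type, lobe)

    @classmethod
    def from_diameter(cls, scan_id, reader_id, center, diameter, nodule_type,
                      lobe=None) -> "Annotation":
        return cls(scan_id, reader_id, center, sphere_volume(diameter),
                   diameter, nodule_type, lobe)


@dataclass(eq=False)
class Prediction:
    """A scored CAD detection: a point in world mm plus a likelihood score."""

    scan_id: str
    center: np.ndarray
    score: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector (world mm)")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(eq=False)
class RegistryRecord:
    """A cancer-registry entry retrospectively localised on a scan."""

    scan_id: str
    center: np.ndarray
    diameter: float
    status: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector (world mm)")
        if self.diameter <= 0:
            raise ValueError("registry diameter must be positive")
        if self.status not in _REGISTRY_STATUSES:
            raise ValueError(
                f"registry status must be one of {_REGISTRY_STATUSES}, "
                f"got {self.status!r}"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"scan_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_scan_manifest(path) -> list[ScanRecord]:
    """Read ``scans.csv``; duplicate ids and unknown categories are hard errors."""
    df = _read_csv(path, ["scan_id", "category"])
    dup = df["scan_id"][df["scan_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate scan_id in manifest: {sorted(set(dup))}")
    records = []
    for i, row in df.iterrows():
        if row["category"] not in CATEGORIES:
            raise ValueError(
                f"row {i + 2}: unknown category {row['category']!r} "
                f"for scan {row['scan_id']!r}"
            )
        pid = row.get("patient_id")
        records.append(
            ScanRecord(str(row["scan_id"]), row["category"],
                       None if pd.isna(pid) else str(pid))
        )
    return records


def write_scan_manifest(scans: Iterable[ScanRecord], path) -> None:
    rows = [
        {"scan_id": s.scan_id, "category": s.category,
         "patient_id": "" if s.patient_id is None else s.patient_id}
        for s in scans
    ]
    pd.DataFrame(rows, columns=["scan_id", "category", "patient_id"]).to_csv(
        path, index=False
    )


def read_annotations(path, manifest: Sequence[ScanRecord] | None = None
                     ) -> dict[str, list[Annotation]]:
    """Read ``annotations.csv`` into a mapping ``reader_id -> annotations``.

    Either ``volume_mm3`` or ``diameter_mm`` must be present; the other is
    derived so every annotation carries both, mutually consistent.  If a
    manifest is given, annotations on unknown scans are hard errors.
    """
    df = _read_csv(path, ["scan_id", "reader_id",
                          "coord_x_mm", "coord_y_mm", "coord_z_mm"])
    has_vol = "volume_mm3" in df.columns
    has_diam = "diameter_mm" in df.columns
    if not has_vol and not has_diam:
        raise ValueError(f"{path}: need a volume_mm3 or diameter_mm column")
    known = None if manifest is None else {s.scan_id for s in manifest}
    out: dict[str, list[Annotation]] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        scan_id = str(row["scan_id"])
        if known is not None and scan_id not in known:
            raise ValueError(f"line {line}: unknown scan_id {scan_id!r}")
        center = np.array([row["coord_x_mm"], row["coord_y_mm"],
                           row["coord_z_mm"]], dtype=float)
        vol = float(row["volume_mm3"]) if has_vol and pd.notna(row.get("volume_mm3")) else None
        diam = float(row["diameter_mm"]) if has_diam and pd.notna(row.get("diameter_mm")) else None
        if vol is None and diam is None:
            raise ValueError(f"line {line}: neither volume nor diameter given")
        if vol is not None and vol <= 0:
            raise ValueError(f"line {line}: non-positive volume {vol}")
        if diam is not None and diam <= 0:
            raise ValueError(f"line {line}: non-positive diameter {diam}")
        if vol is None:
            vol = sphere_volume(diam)
        if diam is None:
            diam = equivalent_diameter(vol)
        lobe = row.get("lobe")
        try:
            ann = Annotation(scan_id, str(row["reader_id"]), center, vol, diam,
                             str(row["nodule_type"]),
                             None if pd.isna(lobe) else str(lobe))
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from exc
        out.setdefault(ann.reader_id, []).append(ann)
    return out


def write_annotations(annotations: Mapping[str, Sequence[Annotation]], path) -> None:
    rows = []
    for reader_id in annotations:
        for a in annotations[reader_id]:
            rows.append({
                "scan_id": a.scan_id, "reader_id": a.reader_id,
                "coord_x_mm": round(a.center[0], 6),
                "coord_y_mm": round(a.center[1], 6),
                "coord_z_mm": round(a.center[2], 6),
                "volume_mm3": round(a.volume, 6),
                "diameter_mm": round(a.equivalent_diameter, 6),
                "nodule_type": a.nodule_type,
                "lobe": "" if a.lobe is None else a.lobe,
            })
    cols = ["scan_id", "reader_id", "coord_x_mm", "coord_y_mm", "coord_z_mm",
            "volume_mm3", "diameter_mm", "nodule_type", "lobe"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_predictions(path, manifest: Sequence[ScanRecord] | None = None
                     ) -> list[Prediction]:
    """Read ``predictions.csv``; scores outside [0, 1] are rejected per row."""
    df = _read_csv(path, ["scan_id", "coord_x_mm", "coord_y_mm", "coord_z_mm",
                          "score"])
    known = None if manifest is None else {s.scan_id for s in manifest}
    preds = []
    for i, row in df.iterrows():
        line = i + 2
        scan_id = str(row["scan_id"])
        if known is not None and scan_id not in known:
            raise ValueError(f"line {line}: unknown scan_id {scan_id!r}")
        center = np.array([row["coord_x_mm"], row["coord_y_mm"],
                           row["coord_z_mm"]], dtype=float)
        if not np.all(np.isfinite(center)):
            raise ValueError(f"line {line}: malformed coordinates")
        try:
            preds.append(Prediction(scan_id, center, float(row["score"])))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {line}: {exc}") from exc
    return preds


def write_predictions(predictions: Iterable[Prediction], path) -> None:
    rows = [
        {"scan_id": p.scan_id,
         "coord_x_mm": round(p.center[0], 6),
         "coord_y_mm": round(p.center[1], 6),
         "coord_z_mm": round(p.center[2], 6),
         "score": round(p.score, 6)}
        for p in predictions
    ]
    cols = ["scan_id", "coord_x_mm", "coord_y_mm", "coord_z_mm", "score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_registry(path, manifest: Sequence[ScanRecord] | None = None
                  ) -> list[RegistryRecord]:
    df = _read_csv(path, ["scan_id", "coord_x_mm", "coord_y_mm", "coord_z_mm",
                          "diameter_mm", "status"])
    known = None if manifest is None else {s.scan_id for s in manifest}
    records = []
    for i, row in df.iterrows():
        line = i + 2
        scan_id = str(row["scan_id"])
        if known is not None and scan_id not in known:
            raise ValueError(f"line {line}: unknown scan_id {scan_id!r}")
        center = np.array([row["coord_x_mm"], row["coord_y_mm"],
                           row["coord_z_mm"]], dtype=float)
        try:
            records.append(RegistryRecord(scan_id, center,
                                          float(row["diameter_mm"]),
                                          str(row["status"])))
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from exc
    return records


def write_registry(records: Iterable[RegistryRecord], path) -> None:
    rows = [
        {"scan_id": r.scan_id,
         "coord_x_mm": round(r.center[0], 6),
         "coord_y_mm": round(r.center[1], 6),
         "coord_z_mm": round(r.center[2], 6),
         "diameter_mm": round(r.diameter, 6),
         "status": r.status}
        for r in records
    ]
    cols = ["scan_id", "coord_x_mm", "coord_y_mm", "coord_z_mm", "diameter_mm",
            "status"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
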