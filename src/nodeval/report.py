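"""Evaluation pipelines and table/point-file writers.

``run_evaluation`` reproduces the per-subset sensitivity table (rows for the
3/4/5-mm diameter thresholds and the actionable-benign / primary-cancer /
metastasis classes, columns for the seven FP rates plus CPM) and exports the
FROC operating points per subset.  ``run_comparison`` reproduces the
reader-vs-AI table with one recalibrated AI row per reader and category,
plus the across-comparison average FROC per category.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import (
    ReferenceStandard,
    SubsetSpec,
    build_reference_standard,
    link_malignancy,
    select_subset,
)
from .froc import (
    DEFAULT_FP_RATES,
    bootstrap_ci,
    calibrate_threshold,
    cpm,
    froc_curve,
    sensitivity_at,
)
from .io import (
    read_annotations,
    read_predictions,
    read_registry,
    read_scan_manifest,
)
from .matching import match_predictions
from .compare import comparison_table

logger = logging.getLogger(__name__)

#: Subset rows of the main sensitivity table.
DEFAULT_SUBSETS = {
    "nodules_ge3mm": SubsetSpec(3.0, "all"),
    "nodules_ge4mm": SubsetSpec(4.0, "all"),
    "nodules_ge5mm": SubsetSpec(5.0, "all"),
    "actionable_benign": SubsetSpec(3.0, "actionable_benign"),
    "primary_cancer": SubsetSpec(3.0, "primary_cancer"),
    "metastasis": SubsetSpec(3.0, "metastasis"),
}


@dataclass
class EvaluationConfig:
    """Paths and analysis parameters for one evaluation run."""

    manifest: str
    annotations: str
    predictions: str
    registry: str
    output_dir: str
    min_agreement: int = 3
    size_bounds: tuple[float, float] = (3.0, 30.0)
    fp_rates: tuple[float, ...] = DEFAULT_FP_RATES
    target_fp: float = 1.0
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0
    subsets: tuple[str, ...] = tuple(DEFAULT_SUBSETS)

    def __post_init__(self) -> None:
        rates = tuple(self.fp_rates)
        if list(rates) != sorted(rates):
            raise ValueError("fp_rates must be sorted ascending")
        self.fp_rates = rates
        unknown = [s for s in self.subsets if s not in DEFAULT_SUBSETS]
        if unknown:
            raise ValueError(f"unknown subset name(s): {unknown}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pct(x: float) -> float:
    """Percentage formatted half-up to 1 decimal."""
    return float((Decimal(repr(100.0 * float(x))))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """p-values to 3 decimals with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def write_reference(ref: ReferenceStandard, nodule_path, exclusion_path) -> None:
    rows = [
        {"nodule_id": n.nodule_id, "scan_id": n.scan_id,
         "coord_x_mm": round(float(n.center[0]), 6),
         "coord_y_mm": round(float(n.center[1]), 6),
         "coord_z_mm": round(float(n.center[2]), 6),
         "volume_mm3": round(n.volume, 6),
         "diameter_mm": round(n.equivalent_diameter, 6),
         "nodule_type": n.nodule_type, "agreement": n.agreement,
         "malignancy": n.malignancy, "actionable": n.actionable,
         "detected_by_panel": n.detected_by_panel}
        for n in ref.nodules
    ]
    pd.DataFrame(rows).to_csv(nodule_path, index=False)
    rows = [
        {"scan_id": e.scan_id,
         "coord_x_mm": round(float(e.center[0]), 6),
         "coord_y_mm": round(float(e.center[1]), 6),
         "coord_z_mm": round(float(e.center[2]), 6),
         "diameter_mm": round(e.equivalent_diameter, 6),
         "agreement": e.agreement, "reason": e.reason}
        for e in ref.exclusion_list
    ]
    cols = ["scan_id", "coord_x_mm", "coord_y_mm", "coord_z_mm",
            "diameter_mm", "agreement", "reason"]
    pd.DataFrame(rows, columns=cols).to_csv(exclusion_path, index=False)


def write_froc_points(curve, path) -> None:
    df = pd.DataFrame({
        "threshold": curve.thresholds,
        "fp_per_scan": curve.fp_per_scan,
        "sensitivity": curve.sensitivity,
    })
    df.to_csv(path, index=False)


def build_linked_reference(config: EvaluationConfig):
    manifest = read_scan_manifest(config.manifest)
    annotations = read_annotations(config.annotations, manifest)
    registry = read_registry(config.registry, manifest)
    ref = build_reference_standard(annotations, manifest,
                                   config.min_agreement, config.size_bounds)
    n_clusters = len(ref.nodules) + len(ref.exclusion_list)
    ref, missed = link_malignancy(ref, registry)
    return manifest, annotations, registry, ref, missed, n_clusters


def run_evaluation(config: EvaluationConfig) -> dict:
    """Full pipeline: reference, matching, per-subset tables with CIs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, annotations, registry, ref, missed, n_clusters = \
        build_linked_reference(config)
    predictions = read_predictions(config.predictions, manifest)
    write_reference(ref, out / "reference.csv", out / "exclusions.csv")

    rows = []
    thresholds = {}
    ss = np.random.SeedSequence(config.seed)
    for name in config.subsets:
        spec = DEFAULT_SUBSETS[name]
        view = select_subset(ref, spec)
        if view.n_targets == 0:
            logger.warning("subset %s has no targets; skipped", name)
            continue
        match = match_predictions(predictions, view)
        curve = froc_curve(match)
        sens = sensitivity_at(curve, config.fp_rates)
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        ci = bootstrap_ci(predictions, view, config.fp_rates,
                          n_boot=config.n_boot, seed=sub_seed)
        thr, achieved = calibrate_threshold(curve, config.target_fp)
        thresholds[name] = {"threshold": thr,
                            "fp_per_scan": achieved.fp_per_scan,
                            "sensitivity": achieved.sensitivity}
        row = {"subset": name, "n_targets": view.n_targets}
        for rate, s, lo, hi in zip(config.fp_rates, sens, ci.lo, ci.hi):
            row[f"sens_at_{rate:g}"] = _pct(s)
            row[f"sens_at_{rate:g}_lo"] = _pct(lo)
            row[f"sens_at_{rate:g}_hi"] = _pct(hi)
        row["cpm"] = _pct(cpm(curve))
        row["cpm_lo"], row["cpm_hi"] = _pct(ci.cpm_lo), _pct(ci.cpm_hi)
        rows.append(row)
        write_froc_points(curve, out / f"froc_points_{name}.csv")
    table = pd.DataFrame(rows)
    table.to_csv(out / "table3.csv", index=False)

    counts = {
        "n_scans": len(manifest),
        "n_clusters": n_clusters,
        "n_included": len(ref.nodules),
        "n_excluded": len(ref.exclusion_list),
        "n_excluded_by_reason": {
            r: sum(e.reason == r for e in ref.exclusion_list)
            for r in ("too_small", "too_large", "minority")
        },
        "n_panel_missed_cancers": len(missed),
        "n_registry_appended": sum(m["action"] == "appended" for m in missed),
        "n_predictions": len(predictions),
    }
    log = {
        "tool": f"nodeval {__version__}",
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "thresholds": thresholds,
    }
    (out / "run.log").write_text(json.dumps(log, indent=2, default=str) + "\n")
    return {"table": table, "counts": counts, "thresholds": thresholds,
            "reference": ref}


def run_comparison(config: EvaluationConfig) -> dict:
    """Reader-vs-AI comparison files plus per-category average FROC curves."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_scan_manifest(config.manifest)
    annotations = read_annotations(config.annotations, manifest)
    registry = read_registry(config.registry, manifest)
    predictions = read_predictions(config.predictions, manifest)
    if len(annotations) < config.min_agreement + 1:
        raise ValueError(
            "reader comparison needs at least min_agreement + 1 readers"
        )
    table, results = comparison_table(
        predictions, annotations, manifest, registry,
        target_fp=config.target_fp, min_agreement=config.min_agreement,
        size_bounds=config.size_bounds, n_boot=config.n_boot,
        n_iter=config.n_perm, seed=config.seed)
    printable = table.copy()
    printable["p_value"] = [format_p(p) for p in table["p_value"]]
    printable.to_csv(out / "comparison.csv", index=False)
    table.to_json(out / "comparison.json", orient="records", indent=2)

    # per-comparison FROC exports and category averages on a shared grid
    grid = np.linspace(0.0, 8.0, 65)
    by_cat: dict[str, list[np.ndarray]] = {}
    for res in results:
        name = f"froc_points_{res.category}_vs_{res.reader_id}.csv"
        write_froc_points(res.ai_curve, out / name)
        interp = np.interp(grid, *_monotone(res.ai_curve))
        by_cat.setdefault(res.category, []).append(interp)
    for cat, curves in by_cat.items():
        mean_curve = np.mean(curves, axis=0)
        pd.DataFrame({"fp_per_scan": grid, "sensitivity": mean_curve}).to_csv(
            out / f"froc_mean_{cat}.csv", index=False)
    log = {
        "tool": f"nodeval {__version__}",
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_comparisons": len(results),
    }
    (out / "comparison_run.log").write_text(
        json.dumps(log, indent=2, default=str) + "\n")
    return {"table": table, "results": results}


def _monotone(curve):
    fp = np.asarray(curve.fp_per_scan)
    sens = np.asarray(curve.sensitivity)
    uniq, first_rev = np.unique(fp[::-1], return_index=True)
    last = len(fp) - 1 - first_rev
    return uniq, sens[last]
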