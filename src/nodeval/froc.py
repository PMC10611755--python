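"""FROC analysis: curves, sensitivity at fixed FP rates, CPM, calibration,
scan-level bootstrap confidence intervals, and the paired permutation test.

The FROC curve sweeps the detection-score threshold and records, per
threshold, the fraction of target nodules whose best hit score clears it
(sensitivity) and the number of false positives clearing it per scan (FP/s).
The summary statistic is the CPM — the mean sensitivity over the seven
predefined rates 0.125, 0.25, 0.5, 1, 2, 4 and 8 FP/s, interpolating
linearly between operating points and carrying the final sensitivity forward
beyond the largest achieved FP rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .consensus import SubsetView
from .io import Prediction
from .matching import MatchResult, match_predictions

__all__ = [
    "DEFAULT_FP_RATES",
    "FROCCurve",
    "OperatingPoint",
    "SensitivityReport",
    "BootstrapCI",
    "PermutationResult",
    "froc_curve",
    "sensitivity_at",
    "cpm",
    "calibrate_threshold",
    "bootstrap_ci",
    "point_sensitivity",
    "paired_permutation_test",
]

#: The seven predefined false-positive rates (per scan) of the CPM.
DEFAULT_FP_RATES = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class OperatingPoint:
    threshold: float
    fp_per_scan: float
    sensitivity: float


@dataclass
class FROCCurve:
    """Ordered operating points, thresholds strictly decreasing."""

    thresholds: np.ndarray   # descending; starts at +inf (zero anchor)
    fp_per_scan: np.ndarray  # non-decreasing
    sensitivity: np.ndarray  # non-decreasing
    n_scans: int
    n_targets: int

    @property
    def points(self) -> list[OperatingPoint]:
        return [OperatingPoint(float(t), float(f), float(s))
                for t, f, s in zip(self.thresholds, self.fp_per_scan,
                                   self.sensitivity)]


@dataclass
class SensitivityReport:
    rates: tuple[float, ...]
    sensitivities: np.ndarray
    cpm: float
    ci: "BootstrapCI | None" = None


@dataclass
class BootstrapCI:
    rates: tuple[float, ...]
    lo: np.ndarray
    hi: np.ndarray
    cpm_lo: float
    cpm_hi: float
    n_boot: int
    n_redrawn: int = 0


@dataclass
class PermutationResult:
    statistic: float
    p_value: float
    n_iter: int
    seed: int


# ---------------------------------------------------------------------------
# Curve construction
# ---------------------------------------------------------------------------

def _curve_arrays(tp_scores: np.ndarray, n_targets: float,
                  fp_scores: np.ndarray, n_scans: float,
                  tp_weights: np.ndarray | None = None,
                  fp_weights: np.ndarray | None = None):
    """(thresholds desc, fp/s, sensitivity) with a (+inf, 0, 0) anchor."""
    scores = np.concatenate([tp_scores, fp_scores])
    thr = np.unique(scores)[::-1]
    if tp_weights is None:
        tp_weights = np.ones_like(tp_scores)
    if fp_weights is None:
        fp_weights = np.ones_like(fp_scores)
    # counts of scores >= t for each threshold t
    order = np.argsort(tp_scores)
    tp_cum = np.concatenate([[0.0], np.cumsum(tp_weights[order][::-1])])
    n_tp = tp_cum[np.searchsorted(-tp_scores[order][::-1], -thr, side="right")]
    order = np.argsort(fp_scores)
    fp_cum = np.concatenate([[0.0], np.cumsum(fp_weights[order][::-1])])
    n_fp = fp_cum[np.searchsorted(-fp_scores[order][::-1], -thr, side="right")]
    thr = np.concatenate([[np.inf], thr])
    sens = np.concatenate([[0.0], n_tp / n_targets])
    fps = np.concatenate([[0.0], n_fp / n_scans])
    return thr, fps, sens


def froc_curve(match: MatchResult) -> FROCCurve:
    """Build the FROC curve from a matching result.

    One operating point per distinct detection score, descending, anchored at
    (+inf threshold, 0 FP/s, 0 sensitivity).
    """
    if match.n_targets == 0:
        raise ValueError(
            "no target nodules: FROC sensitivity is undefined; summarise the "
            "FP rate alone instead"
        )
    if match.n_scans <= 0:
        raise ValueError("n_scans must be positive")
    thr, fps, sens = _curve_arrays(match.tp_scores, match.n_targets,
                                   match.fp_scores, match.n_scans)
    return FROCCurve(thr, fps, sens, match.n_scans, match.n_targets)


def _interp_rates(fp: np.ndarray, sens: np.ndarray,
                  rates: Sequence[float]) -> np.ndarray:
    """Linear interpolation of sensitivity in FP/s; constant beyond the ends.

    Duplicate FP/s values collapse to the highest sensitivity attained there
    (the achievable operating point).
    """
    fp = np.asarray(fp, dtype=float)
    sens = np.asarray(sens, dtype=float)
    # keep the last occurrence per fp value (sens is non-decreasing)
    uniq, first_idx_rev = np.unique(fp[::-1], return_index=True)
    last_idx = len(fp) - 1 - first_idx_rev
    return np.interp(rates, uniq, sens[last_idx])


def sensitivity_at(curve: FROCCurve,
                   fp_rates: Sequence[float] = DEFAULT_FP_RATES) -> np.ndarray:
    """Sensitivity at the queried FP/s values (fractions in [0, 1])."""
    rates = np.asarray(fp_rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("fp_rates must be positive")
    return _interp_rates(curve.fp_per_scan, curve.sensitivity, rates)


def cpm(curve: FROCCurve) -> float:
    """Mean sensitivity over the seven predefined FP rates."""
    return float(np.mean(sensitivity_at(curve, DEFAULT_FP_RATES)))


def calibrate_threshold(curve: FROCCurve, target_fp_per_scan: float = 1.0
                        ) -> tuple[float, OperatingPoint]:
    """Smallest threshold whose FP/s does not exceed the target.

    Returns the threshold together with the achieved operating point (the
    largest admissible one).  If even the first real operating point exceeds
    the target, the zero anchor is returned (sensitivity 0).
    """
    if target_fp_per_scan <= 0:
        raise ValueError("target FP/s must be positive")
    if len(curve.thresholds) == 0:
        raise ValueError("empty FROC curve")
    ok = np.nonzero(curve.fp_per_scan <= target_fp_per_scan)[0]
    i = int(ok[-1])
    return float(curve.thresholds[i]), OperatingPoint(
        float(curve.thresholds[i]), float(curve.fp_per_scan[i]),
        float(curve.sensitivity[i]))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _per_scan_scores(match: MatchResult, view: SubsetView):
    """Per-scan detected-target scores, target counts, and FP scores."""
    scan_ids = [s.scan_id for s in view.scans]
    index = {sid: i for i, sid in enumerate(scan_ids)}
    nod_scan = {n.nodule_id: n.scan_id for n in view.targets}
    tp_scores, tp_scan = [], []
    n_targets = np.zeros(len(scan_ids), dtype=float)
    for nid in match.target_ids:
        i = index[nod_scan[nid]]
        n_targets[i] += 1
        s = match.best_score[nid]
        if s is not None:
            tp_scores.append(s)
            tp_scan.append(i)
    fp_scores, fp_scan = [], []
    for r in match.records:
        if r.label == "FP":
            fp_scores.append(r.prediction.score)
            fp_scan.append(index[r.prediction.scan_id])
    return (np.asarray(tp_scores), np.asarray(tp_scan, dtype=int), n_targets,
            np.asarray(fp_scores), np.asarray(fp_scan, dtype=int))


def bootstrap_ci(predictions: Sequence[Prediction], view: SubsetView,
                 fp_rates: Sequence[float] = DEFAULT_FP_RATES,
                 n_boot: int = 1000, seed: int = 0) -> BootstrapCI:
    """Scan-level bootstrap 95% CIs for per-rate sensitivities and the CPM.

    Each replicate resamples scan ids with replacement; a scan drawn k times
    contributes its targets and predictions k times.  The full FROC curve and
    the rate interpolation are recomputed per replicate; intervals are the
    2.5th/97.5th percentiles.  Replicates with zero targets are redrawn (a
    counter is kept).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    match = match_predictions(predictions, view)
    if match.n_targets == 0:
        raise ValueError("no target nodules in view")
    tp_scores, tp_scan, targets_per_scan, fp_scores, fp_scan = \
        _per_scan_scores(match, view)
    n = view.n_scans
    rng = np.random.default_rng(seed)
    rates = np.asarray(fp_rates, dtype=float)
    sens_rep = np.empty((n_boot, len(rates)))
    cpm_rep = np.empty(n_boot)
    cpm_rates = np.asarray(DEFAULT_FP_RATES)
    redrawn = 0
    for b in range(n_boot):
        while True:
            draw = rng.integers(0, n, n)
            mult = np.bincount(draw, minlength=n).astype(float)
            total_targets = float(mult @ targets_per_scan)
            if total_targets > 0:
                break
            redrawn += 1
        thr, fps, sens = _curve_arrays(tp_scores, total_targets, fp_scores, n,
                                       tp_weights=mult[tp_scan],
                                       fp_weights=mult[fp_scan])
        sens_rep[b] = _interp_rates(fps, sens, rates)
        cpm_rep[b] = np.mean(_interp_rates(fps, sens, cpm_rates))
    lo, hi = np.percentile(sens_rep, [2.5, 97.5], axis=0)
    cpm_lo, cpm_hi = np.percentile(cpm_rep, [2.5, 97.5])
    return BootstrapCI(tuple(rates), lo, hi, float(cpm_lo), float(cpm_hi),
                       n_boot, redrawn)


# ---------------------------------------------------------------------------
# Point estimates and significance
# ---------------------------------------------------------------------------

def point_sensitivity(n_detected: int, n_targets: int) -> float:
    """Detection fraction as a percentage, rounded half-up to 1 decimal."""
    if n_targets <= 0:
        raise ValueError("n_targets must be positive")
    if not 0 <= n_detected <= n_targets:
        raise ValueError("n_detected must be between 0 and n_targets")
    pct = Decimal(100 * n_detected) / Decimal(n_targets)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def paired_permutation_test(detect_a: Sequence[int], detect_b: Sequence[int],
                            n_iter: int = 1000, seed: int = 0
                            ) -> PermutationResult:
    """Two-sided paired permutation test on per-nodule detection vectors.

    The statistic is the difference in detection fractions; the null is
    generated by independently swapping each (a, b) pair, i.e. sign-flipping
    the per-nodule differences.  The p-value uses the add-one correction
    ``(1 + #{|T_perm| >= |T_obs|}) / (1 + n_iter)`` and is therefore always
    positive.
    """
    a = np.asarray(detect_a, dtype=float)
    b = np.asarray(detect_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("detection vectors must be 1-d and of equal length")
    if len(a) == 0:
        raise ValueError("empty detection vectors")
    d = a - b
    t_obs = float(np.mean(d))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, len(d)))
    t_perm = (signs * d).mean(axis=1)
    exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + exceed) / (1 + n_iter)
    return PermutationResult(t_obs, p, n_iter, seed)
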