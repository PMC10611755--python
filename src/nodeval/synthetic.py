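"""Synthetic cohorts, reader panels, and CAD outputs for end-to-end testing.

The generator emulates the statistical structure of a two-hospital nodule
validation study: four balanced scan categories (stage I lung cancer,
pulmonary metastases, actionable benign nodules, normal), roughly two
nodules per scan with lognormal diameters (median 6.6 mm, IQR 4.7-11.9 mm),
a five-type mixture dominated by solid nodules, and a cap of 15 metastases
per scan.  Simulated readers detect each nodule with a logistic-in-log-
diameter probability, mark it with localisation jitter and size-measurement
noise, and add Poisson false-positive marks per scan; the simulated CAD
emits scored candidates with a tunable FROC profile.

Nodules are placed with guaranteed pairwise separation so that clustering
and matching have an unambiguous ground truth; real anatomy (attached or
juxtapleural lesions) is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .consensus import ReferenceStandard, ReferenceNodule, _is_actionable
from .io import (
    Annotation,
    CATEGORIES,
    NODULE_TYPES,
    Prediction,
    RegistryRecord,
    ScanRecord,
    sphere_volume,
)

__all__ = [
    "LognormalSpec",
    "CohortConfig",
    "ReaderProfile",
    "CADProfile",
    "TrueNodule",
    "GroundTruthCohort",
    "generate_cohort",
    "simulate_readers",
    "simulate_cad",
    "default_reader_panel",
    "perfect_reader_panel",
]

#: Phi^-1(0.75); links a lognormal's IQR to its log-scale sigma.
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class LognormalSpec:
    """A lognormal parameterised by its median and interquartile range."""

    median: float
    iqr: tuple[float, float]

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        lo, hi = self.iqr
        return math.log(hi / lo) / (2.0 * _Z75)

    def sample(self, rng: np.random.Generator, size=None,
               clip: tuple[float, float] | None = None):
        x = rng.lognormal(self.mu, self.sigma, size)
        if clip is not None:
            # resample out-of-range draws (truncation, not clamping)
            lo, hi = clip
            x = np.atleast_1d(x)
            bad = (x < lo) | (x > hi)
            while bad.any():
                x[bad] = rng.lognormal(self.mu, self.sigma, int(bad.sum()))
                bad = (x < lo) | (x > hi)
            if size is None:
                return float(x[0])
        return x


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults reproduce the published cohort structure: 25 scans per category,
    a median of 2 nodules per scan (IQR 1-4), lognormal diameters with median
    6.6 mm and IQR 4.7-11.9 mm, the observed five-type mixture, and at most
    15 metastases per scan.
    """

    scans_per_category: tuple[int, int, int, int] = (25, 25, 25, 25)
    nodules_per_scan: LognormalSpec = LognormalSpec(2.0, (1.0, 4.0))
    diameter_dist: LognormalSpec = LognormalSpec(6.6, (4.7, 11.9))
    metastasis_diameter_dist: LognormalSpec = LognormalSpec(7.0, (4.7, 11.9))
    primary_diameter_dist: LognormalSpec = LognormalSpec(18.0, (13.0, 24.0))
    metastases_per_scan: LognormalSpec = LognormalSpec(4.0, (2.0, 8.0))
    type_mixture: tuple[float, ...] = (0.815, 0.063, 0.033, 0.056, 0.033)
    metastasis_cap: int = 15
    scene_box: tuple[float, float, float] = (280.0, 280.0, 240.0)
    min_separation_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_mixture) - 1.0) > 1e-9:
            raise ValueError("type_mixture must sum to 1")
        if self.min_separation_factor <= 1.0:
            raise ValueError("min_separation_factor must exceed 1")


@dataclass(eq=False)
class TrueNodule:
    """A latent ground-truth lesion."""

    scan_id: str
    center: np.ndarray
    diameter: float
    nodule_type: str
    malignancy: str = "benign"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return sphere_volume(self.diameter)


@dataclass
class GroundTruthCohort:
    scans: list[ScanRecord]
    nodules: list[TrueNodule]
    seed: int
    scene_box: tuple[float, float, float] = (280.0, 280.0, 240.0)

    def nodules_on(self, scan_id: str) -> list[TrueNodule]:
        return [n for n in self.nodules if n.scan_id == scan_id]

    def registry(self) -> list[RegistryRecord]:
        """Registry records for every malignant latent nodule."""
        return [
            RegistryRecord(n.scan_id, n.center.copy(), n.diameter, n.malignancy)
            for n in self.nodules if n.malignancy != "benign"
        ]

    def to_reference(self, min_agreement: int = 3, n_readers: int = 5,
                     size_bounds: tuple[float, float] = (3.0, 30.0)
                     ) -> ReferenceStandard:
        """The latent truth cast as a reference standard (oracle use only)."""
        from .consensus import ExcludedFinding

        lo, hi = size_bounds
        nodules, excluded = [], []
        counts: dict[str, int] = {}
        for n in self.nodules:
            if lo <= n.diameter <= hi:
                k = counts.get(n.scan_id, 0) + 1
                counts[n.scan_id] = k
                rn = ReferenceNodule(f"{n.scan_id}_n{k:03d}", n.scan_id,
                                     n.center.copy(), n.volume, n.diameter,
                                     n.nodule_type, n_readers, n.malignancy)
                rn.actionable = _is_actionable(rn)
                nodules.append(rn)
            else:
                reason = "too_small" if n.diameter < lo else "too_large"
                excluded.append(ExcludedFinding(n.scan_id, n.center.copy(),
                                                n.diameter, n_readers, reason,
                                                n.volume, n.nodule_type))
        return ReferenceStandard(list(self.scans), nodules, excluded,
                                 min_agreement, n_readers)


@dataclass(frozen=True)
class ReaderProfile:
    """Generative model of one simulated radiologist.

    Detection probability is ``logistic(a + b ln d)`` scaled by a per-type
    multiplier; detected nodules are marked with isotropic Gaussian jitter
    (sd = ``jitter_frac`` x radius, split over axes) and relative size noise;
    false-positive marks arrive Poisson per scan with small diameters.
    """

    reader_id: str
    detect_a: float = -2.0
    detect_b: float = 2.0
    type_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in NODULE_TYPES})
    jitter_frac: float = 0.2
    size_noise: float = 0.1
    fp_rate: float = 0.3
    fp_diameter_dist: LognormalSpec = LognormalSpec(4.0, (3.0, 5.5))

    def detection_probability(self, diameter: float, nodule_type: str) -> float:
        p = 1.0 / (1.0 + math.exp(-(self.detect_a
                                    + self.detect_b * math.log(diameter))))
        return float(np.clip(p * self.type_multiplier.get(nodule_type, 1.0),
                             0.0, 1.0))


@dataclass(frozen=True)
class CADProfile:
    """Generative model of the simulated CAD's scored output.

    Per nodule a candidate is emitted with probability ``emission_prob`` and
    scored ``clip01(logistic(alpha + beta ln d + gamma_type + eps))`` with
    ``eps ~ N(0, sigma)``; false positives arrive Poisson per scan with
    Beta-distributed (low-concentrated) scores.
    """

    emission_prob: float = 0.95
    alpha: float = -1.0
    beta: float = 1.2
    gamma_type: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in NODULE_TYPES})
    sigma: float = 0.6
    fp_rate: float = 4.0
    fp_beta: tuple[float, float] = (1.2, 5.0)

    @classmethod
    def calibrated(cls, sensitivity_at_1fps: float = 0.9,
                   fp_rate: float = 4.0) -> "CADProfile":
        """Profile whose sensitivity at 1 FP/s equals the emission rate.

        Emitted candidates score in [0.6, 1] while FP scores follow
        Beta(1, 8), so the threshold achieving ``fp_rate * P(fp >= t) = 1``
        sits far below every candidate score: the system detects exactly the
        emitted fraction at 1 FP/s.
        """
        return cls(emission_prob=sensitivity_at_1fps, alpha=math.inf,
                   beta=0.0, sigma=0.0, fp_rate=fp_rate, fp_beta=(1.0, 8.0))

    def tp_score(self, rng: np.random.Generator, diameter: float,
                 nodule_type: str) -> float:
        if math.isinf(self.alpha):  # calibrated profile: high flat scores
            return float(rng.uniform(0.6, 1.0))
        z = (self.alpha + self.beta * math.log(diameter)
             + self.gamma_type.get(nodule_type, 0.0)
             + (rng.normal(0.0, self.sigma) if self.sigma > 0 else 0.0))
        return float(np.clip(1.0 / (1.0 + math.exp(-z)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _stream(seed: int, offset: int) -> np.random.Generator:
    # fixed per-stage offsets so stages can be regenerated independently
    return np.random.default_rng(np.random.SeedSequence([seed, offset]))


def _place(rng, existing: list[TrueNodule], radius: float,
           box: tuple[float, float, float], factor: float,
           max_tries: int = 500) -> np.ndarray:
    half = np.asarray(box) / 2.0
    for _ in range(max_tries):
        c = rng.uniform(-half, half)
        ok = all(
            np.linalg.norm(c - n.center) > factor * (radius + n.radius)
            for n in existing
        )
        if ok:
            return c
    raise RuntimeError(
        "could not place a nodule with the required separation; "
        "increase scene_box"
    )


def _background_count(rng, cfg: CohortConfig) -> int:
    return max(0, int(round(cfg.nodules_per_scan.sample(rng))) - 1)


def _draw_type(rng, cfg: CohortConfig, allowed: Sequence[str] | None = None
               ) -> str:
    p = np.asarray(cfg.type_mixture, dtype=float)
    types = list(NODULE_TYPES)
    if allowed is not None:
        mask = np.array([t in allowed for t in types])
        p = p * mask
        p = p / p.sum()
    return types[int(rng.choice(len(types), p=p))]


def generate_cohort(config: CohortConfig | None = None) -> GroundTruthCohort:
    """Draw a ground-truth cohort; deterministic given ``config.seed``.

    Category rules: stage-I-cancer scans carry exactly one primary cancer
    (<= 30 mm); metastasis scans carry 1..cap metastases; actionable-benign
    scans carry at least one benign nodule >= 5 mm that is neither calcified
    nor perifissural; normal scans carry only nodules < 5 mm, if any.
    """
    cfg = config or CohortConfig()
    rng = _stream(cfg.seed, 1)
    scans: list[ScanRecord] = []
    nodules: list[TrueNodule] = []
    idx = 0
    for cat, n_scans in zip(CATEGORIES, cfg.scans_per_category):
        for _ in range(n_scans):
            idx += 1
            scan_id = f"scan{idx:04d}"
            scans.append(ScanRecord(scan_id, cat, f"pat{idx:04d}"))
            local: list[TrueNodule] = []

            def add(diameter, ntype, malignancy="benign"):
                c = _place(rng, local, diameter / 2.0, cfg.scene_box,
                           cfg.min_separation_factor)
                local.append(TrueNodule(scan_id, c, float(diameter), ntype,
                                        malignancy))

            if cat == "stage1_cancer":
                d = cfg.primary_diameter_dist.sample(rng, clip=(8.0, 30.0))
                add(d, _draw_type(rng, cfg,
                                  ("solid", "part_solid", "non_solid")),
                    "primary_cancer")
                for _ in range(_background_count(rng, cfg)):
                    add(cfg.diameter_dist.sample(rng, clip=(2.5, 30.0)),
                        _draw_type(rng, cfg))
            elif cat == "metastases":
                m = int(round(cfg.metastases_per_scan.sample(rng)))
                m = min(max(m, 1), cfg.metastasis_cap)
                for _ in range(m):
                    add(cfg.metastasis_diameter_dist.sample(rng,
                                                            clip=(3.0, 25.0)),
                        "solid", "metastasis")
            elif cat == "actionable_benign":
                d = cfg.diameter_dist.sample(rng, clip=(5.0, 30.0))
                add(d, _draw_type(rng, cfg,
                                  ("solid", "part_solid", "non_solid")))
                for _ in range(_background_count(rng, cfg)):
                    add(cfg.diameter_dist.sample(rng, clip=(2.5, 30.0)),
                        _draw_type(rng, cfg))
            else:  # normal: only sub-5-mm nodules, possibly none
                k = max(0, int(round(cfg.nodules_per_scan.sample(rng))) - 1)
                for _ in range(k):
                    add(cfg.diameter_dist.sample(rng, clip=(2.5, 4.95)),
                        _draw_type(rng, cfg))
            nodules.extend(local)
    return GroundTruthCohort(scans, nodules, cfg.seed, cfg.scene_box)


# ---------------------------------------------------------------------------
# Observer and CAD simulation
# ---------------------------------------------------------------------------

def default_reader_panel() -> list[ReaderProfile]:
    """Five heterogeneous readers bracketing the published panel's range
    (FP/s roughly 0.1-0.8; metastasis-sized sensitivity from ~30% to ~90%).
    """
    return [
        ReaderProfile("r1", detect_a=-1.5, detect_b=2.0, fp_rate=0.7),
        ReaderProfile("r2", detect_a=-5.5, detect_b=2.2, fp_rate=0.1),
        ReaderProfile("r3", detect_a=-3.2, detect_b=2.2, fp_rate=0.2),
        ReaderProfile("r4", detect_a=-4.5, detect_b=2.2, fp_rate=0.5),
        ReaderProfile("r5", detect_a=-1.0, detect_b=2.0, fp_rate=0.8),
    ]


def perfect_reader_panel(n: int = 5) -> list[ReaderProfile]:
    """Readers that detect everything exactly: no misses, jitter, or FPs."""
    return [
        ReaderProfile(f"r{i + 1}", detect_a=50.0, detect_b=0.0,
                      jitter_frac=0.0, size_noise=0.0, fp_rate=0.0)
        for i in range(n)
    ]


def simulate_readers(cohort: GroundTruthCohort,
                     profiles: Sequence[ReaderProfile],
                     seed: int | None = None
                     ) -> dict[str, list[Annotation]]:
    """Draw per-reader annotation sets from the cohort; deterministic."""
    if not profiles:
        raise ValueError("need at least one reader profile")
    base = cohort.seed if seed is None else seed
    out: dict[str, list[Annotation]] = {}
    for k, prof in enumerate(profiles):
        rng = _stream(base, 1000 + k)
        anns: list[Annotation] = []
        for n in cohort.nodules:
            p = prof.detection_probability(n.diameter, n.nodule_type)
            if rng.random() >= p:
                continue
            center = n.center
            if prof.jitter_frac > 0:
                sd = prof.jitter_frac * n.radius / math.sqrt(3.0)
                center = center + rng.normal(0.0, sd, 3)
            d = n.diameter
            if prof.size_noise > 0:
                d = max(0.5, d * (1.0 + rng.normal(0.0, prof.size_noise)))
            anns.append(Annotation.from_diameter(n.scan_id, prof.reader_id,
                                                 center, d, n.nodule_type))
        for scan in cohort.scans:
            n_fp = rng.poisson(prof.fp_rate)
            truths = cohort.nodules_on(scan.scan_id)
            for _ in range(n_fp):
                d = prof.fp_diameter_dist.sample(rng, clip=(2.0, 12.0))
                c = _place(rng, truths, d / 2.0, cohort.scene_box, 2.0)
                anns.append(Annotation.from_diameter(scan.scan_id,
                                                     prof.reader_id, c, d,
                                                     "solid"))
        out[prof.reader_id] = anns
    return out


def simulate_cad(cohort: GroundTruthCohort,
                 profile: CADProfile | None = None,
                 seed: int | None = None) -> list[Prediction]:
    """Draw a scored CAD prediction set from the cohort; deterministic."""
    prof = profile or CADProfile()
    base = cohort.seed if seed is None else seed
    rng = _stream(base, 2000)
    preds: list[Prediction] = []
    for n in cohort.nodules:
        if rng.random() >= prof.emission_prob:
            continue
        score = prof.tp_score(rng, n.diameter, n.nodule_type)
        # small localisation offset, always within the nodule radius
        offset = rng.normal(0.0, 0.15 * n.radius / math.sqrt(3.0), 3)
        norm = float(np.linalg.norm(offset))
        if norm > 0.8 * n.radius:
            offset *= 0.8 * n.radius / norm
        preds.append(Prediction(n.scan_id, n.center + offset, score))
    a, b = prof.fp_beta
    for scan in cohort.scans:
        n_fp = rng.poisson(prof.fp_rate)
        truths = cohort.nodules_on(scan.scan_id)
        for _ in range(n_fp):
            c = _place(rng, truths, 2.0, cohort.scene_box, 2.0)
            preds.append(Prediction(scan.scan_id, c, float(rng.beta(a, b))))
    return preds
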