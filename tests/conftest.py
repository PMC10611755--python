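"""Shared builders for synthetic scenes used across the test suite."""

import math

import numpy as np
import pytest

from nodeval import (
    Annotation,
    Prediction,
    ReferenceNodule,
    ScanRecord,
    SubsetView,
)
from nodeval.consensus import IgnoreRegion
from nodeval.consensus import _is_actionable  # noqa: F401  (re-export for tests)


def ann(scan="s1", reader="r1", center=(0, 0, 0), d=6.0, ntype="solid"):
    return Annotation.from_diameter(scan, reader, np.asarray(center, float),
                                    d, ntype)


def nodule(nid, scan="s1", center=(0, 0, 0), d=10.0, ntype="solid",
           malignancy="benign", agreement=5):
    n = ReferenceNodule(nid, scan, np.asarray(center, float),
                        math.pi / 6 * d**3, d, ntype, agreement, malignancy)
    n.actionable = _is_actionable(n)
    return n


def pred(scan="s1", center=(0, 0, 0), score=0.5):
    return Prediction(scan, np.asarray(center, float), score)


def make_view(targets, ignore=(), n_scans=None, scan_ids=None):
    """A SubsetView over simple synthetic scans named s1..sN."""
    if scan_ids is None:
        ids = sorted({t.scan_id for t in targets}
                     | {e.scan_id for e in ignore})
        if n_scans is not None:
            ids = [f"s{i + 1}" for i in range(n_scans)]
        scan_ids = ids
    scans = [ScanRecord(sid, "normal") for sid in scan_ids]
    regions = [
        e if isinstance(e, IgnoreRegion)
        else IgnoreRegion(e[0], tuple(np.asarray(e[1], float)), e[2])
        for e in ignore
    ]
    return SubsetView(list(targets), regions, scans)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
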