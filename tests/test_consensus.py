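"""Consensus building: clustering, majority vote, size gate, registry linkage."""

import itertools
import math

import numpy as np
import pytest

import nodeval as nv
from nodeval.consensus import cluster_annotations

from conftest import ann


def _ids(clusters):
    return {frozenset((a.reader_id, tuple(a.center)) for a in c)
            for c in clusters}


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_coincident_marks_form_one_cluster():
    anns = [ann(reader=f"r{i}", center=(10, 20, 30), d=6) for i in range(5)]
    clusters = cluster_annotations(anns)
    assert len(clusters) == 1 and len(clusters[0]) == 5


def test_distant_marks_stay_separate():
    anns = [ann(reader="r1", center=(0, 0, 0), d=6),
            ann(reader="r2", center=(0, 0, 0), d=6),
            ann(reader="r3", center=(40, 0, 0), d=6)]
    assert _ids(cluster_annotations(anns)) == {
        frozenset({("r1", (0., 0., 0.)), ("r2", (0., 0., 0.))}),
        frozenset({("r3", (40., 0., 0.))}),
    }


def test_same_reader_marks_never_merge():
    anns = [ann(reader="r1", center=(0, 0, 0), d=8),
            ann(reader="r1", center=(1, 0, 0), d=8)]
    assert len(cluster_annotations(anns)) == 2


def _oracle_partition(anns):
    """Exhaustive partition enumeration with validity pruning.

    A block is valid when every pair satisfies the merge predicate and no
    reader appears twice.  Among valid partitions, minimise the number of
    blocks, then the total within-block pair distance.
    """
    def compatible(block, a):
        return all(
            a.reader_id != b.reader_id
            and np.linalg.norm(a.center - b.center) <= max(a.radius, b.radius)
            for b in block
        )

    best = [None]

    def cost(blocks):
        tot = sum(
            float(np.linalg.norm(x.center - y.center))
            for blk in blocks for x, y in itertools.combinations(blk, 2)
        )
        return (len(blocks), tot)

    def rec(i, blocks):
        if i == len(anns):
            c = cost(blocks)
            if best[0] is None or c < best[0][0]:
                best[0] = (c, [list(b) for b in blocks])
            return
        a = anns[i]
        for b in blocks:
            if compatible(b, a):
                b.append(a)
                rec(i + 1, blocks)
                b.pop()
        blocks.append([a])
        rec(i + 1, blocks)
        blocks.pop()

    rec(0, [])
    return best[0][1]


def test_clustering_matches_exhaustive_oracle(rng):
    """Random well-separated scenes: greedy merging equals the brute-force
    optimal grouping (at most 12 jittered marks per scene)."""
    readers = ["r1", "r2", "r3", "r4", "r5"]
    for _ in range(20):
        n_sites = rng.integers(1, 5)
        centers = rng.uniform(-120, 120, (n_sites, 3))
        while n_sites > 1 and np.min(
                [np.linalg.norm(a - b) for a, b in
                 itertools.combinations(centers, 2)]) < 60:
            centers = rng.uniform(-120, 120, (n_sites, 3))
        anns = []
        for c in centers:
            d = rng.uniform(5, 10)
            k = rng.integers(1, 4)
            for r in rng.choice(readers, size=k, replace=False):
                jitter = rng.normal(0, 0.08 * d, 3)
                anns.append(ann(reader=str(r), center=c + jitter,
                                d=d * rng.uniform(0.9, 1.1)))
        got = _ids(cluster_annotations(anns))
        want = _ids(_oracle_partition(anns))
        assert got == want


def test_clustering_invariant_under_input_order(rng):
    anns = [ann(reader=f"r{i % 5}", center=rng.uniform(-80, 80, 3),
                d=rng.uniform(4, 12)) for i in range(15)]
    base = _ids(cluster_annotations(anns))
    for _ in range(5):
        perm = list(rng.permutation(len(anns)))
        assert _ids(cluster_annotations([anns[i] for i in perm])) == base


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _panel(marks):
    """marks: list of (reader, center, d[, type]) -> per-reader mapping."""
    out = {}
    for m in marks:
        r, c, d = m[:3]
        ntype = m[3] if len(m) > 3 else "solid"
        out.setdefault(r, []).append(ann(reader=r, center=c, d=d, ntype=ntype))
    for r in ("r1", "r2", "r3", "r4", "r5"):
        out.setdefault(r, [])
    return out


MANIFEST = [nv.ScanRecord("s1", "normal")]


def test_minority_cluster_is_excluded():
    panel = _panel([("r1", (0, 0, 0), 6), ("r2", (0, 0, 0), 6)])
    ref = nv.build_reference_standard(panel, MANIFEST)
    assert ref.nodules == []
    [e] = ref.exclusion_list
    assert e.reason == "minority" and e.agreement == 2


def test_consensus_measurements_are_means():
    panel = _panel([(f"r{i + 1}", (0, 0, 0), d)
                    for i, d in enumerate([4, 5, 6, 5, 5])])
    ref = nv.build_reference_standard(panel, MANIFEST)
    [n] = ref.nodules
    assert n.equivalent_diameter == pytest.approx(5.0)
    assert n.agreement == 5
    assert n.volume == pytest.approx(
        np.mean([math.pi / 6 * d**3 for d in [4, 5, 6, 5, 5]]))


def test_size_gate_on_averaged_diameter():
    panel = _panel([(f"r{i + 1}", (0, 0, 0), d)
                    for i, d in enumerate([2.8, 2.8, 2.8, 2.8])])
    ref = nv.build_reference_standard(panel, MANIFEST)
    [e] = ref.exclusion_list
    assert e.reason == "too_small" and ref.nodules == []


def test_oversize_cluster_excluded_as_too_large():
    panel = _panel([(f"r{i + 1}", (0, 0, 0), 32) for i in range(5)])
    ref = nv.build_reference_standard(panel, MANIFEST)
    [e] = ref.exclusion_list
    assert e.reason == "too_large"


def test_min_agreement_above_panel_size_is_error():
    with pytest.raises(ValueError, match="min_agreement"):
        nv.build_reference_standard(_panel([]), MANIFEST, min_agreement=6)


def _random_panel(rng, n_scans=6):
    manifest = [nv.ScanRecord(f"s{i + 1}", "normal") for i in range(n_scans)]
    panel = {f"r{i + 1}": [] for i in range(5)}
    for s in manifest:
        for _ in range(rng.integers(0, 4)):
            c = rng.uniform(-100, 100, 3)
            d = rng.uniform(2, 12)
            for r in rng.choice(sorted(panel), rng.integers(1, 6),
                                replace=False):
                panel[str(r)].append(ann(scan=s.scan_id, reader=str(r),
                                         center=c + rng.normal(0, 0.05 * d, 3),
                                         d=d))
    return panel, manifest


def test_cluster_conservation_and_agreement_monotonicity(rng):
    """n_clusters = n_included + n_excluded; included count is
    non-increasing in min_agreement, union at 1, intersection at 5."""
    for _ in range(10):
        panel, manifest = _random_panel(rng)
        n_clusters = sum(
            len(cluster_annotations([a for r in sorted(panel)
                                     for a in panel[r] if a.scan_id == s.scan_id]))
            for s in manifest
        )
        sizes = []
        for k in range(1, 6):
            ref = nv.build_reference_standard(panel, manifest, min_agreement=k)
            assert len(ref.nodules) + len(ref.exclusion_list) == n_clusters
            sizes.append(len(ref.nodules))
        assert sizes == sorted(sizes, reverse=True)


def test_identical_readers_leave_no_minority_findings(rng):
    marks = [(rng.uniform(-100, 100, 3), rng.uniform(2, 12))
             for _ in range(8)]
    # keep sites separated so each mark set is its own lesion
    marks = [(np.array([60.0 * i, 0, 0]), d) for i, (_, d) in enumerate(marks)]
    panel = {f"r{j + 1}": [ann(reader=f"r{j + 1}", center=c, d=d)
                           for c, d in marks] for j in range(5)}
    ref = nv.build_reference_standard(panel, MANIFEST)
    size_valid = [d for _, d in marks if 3 <= d <= 30]
    assert len(ref.nodules) == len(size_valid)
    assert all(e.reason != "minority" for e in ref.exclusion_list)
    assert all(n.agreement == 5 for n in ref.nodules)


def test_type_plurality_with_priority_tiebreak():
    panel = _panel([("r1", (0, 0, 0), 6, "solid"),
                    ("r2", (0, 0, 0), 6, "part_solid"),
                    ("r3", (0, 0, 0), 6, "part_solid"),
                    ("r4", (0, 0, 0), 6, "solid")])
    ref = nv.build_reference_standard(panel, MANIFEST)
    assert ref.nodules[0].nodule_type == "solid"  # tie -> solid wins


# ---------------------------------------------------------------------------
# Malignancy linkage
# ---------------------------------------------------------------------------

def _full_reference(extra=()):
    panel = _panel([(f"r{i + 1}", (0, 0, 0), 8) for i in range(5)]
                   + list(extra))
    return nv.build_reference_standard(panel, MANIFEST), panel


def test_registry_record_relabels_covering_nodule():
    ref, _ = _full_reference()
    reg = [nv.RegistryRecord("s1", (1, 0, 0), 8.0, "primary_cancer")]
    linked, missed = nv.link_malignancy(ref, reg)
    [n] = linked.nodules
    assert n.malignancy == "primary_cancer" and not n.actionable
    assert missed == []


def test_empty_registry_keeps_everything_benign():
    ref, _ = _full_reference()
    linked, missed = nv.link_malignancy(ref, [])
    assert all(n.malignancy == "benign" for n in linked.nodules)
    assert missed == []


def test_far_registry_record_is_appended_as_missed_cancer():
    ref, _ = _full_reference()
    reg = [nv.RegistryRecord("s1", (50, 0, 0), 6.0, "metastasis")]
    linked, missed = nv.link_malignancy(ref, reg)
    assert len(missed) == 1
    assert len(linked.nodules) == len(ref.nodules) + 1
    added = [n for n in linked.nodules if not n.detected_by_panel]
    assert added[0].malignancy == "metastasis"


def test_registry_promotes_minority_cluster():
    ref, _ = _full_reference(extra=[("r2", (60, 0, 0), 6),
                                    ("r4", (60, 0, 0), 6)])
    assert any(e.reason == "minority" for e in ref.exclusion_list)
    reg = [nv.RegistryRecord("s1", (60, 0, 0), 6.0, "metastasis")]
    linked, missed = nv.link_malignancy(ref, reg)
    assert missed[0]["action"] == "promoted_minority"
    promoted = linked.nodule(missed[0]["nodule_id"])
    assert promoted.agreement == 2 and not promoted.detected_by_panel
    assert not any(e.reason == "minority" for e in linked.exclusion_list)


# ---------------------------------------------------------------------------
# Subsets
# ---------------------------------------------------------------------------

def _ref_with_diameters(diams, types=None):
    types = types or ["solid"] * len(diams)
    panel = {f"r{j + 1}": [ann(reader=f"r{j + 1}", center=(60 * i, 0, 0),
                               d=d, ntype=t)
                           for i, (d, t) in enumerate(zip(diams, types))]
             for j in range(5)}
    return nv.build_reference_standard(panel, MANIFEST)


def test_full_subset_is_identity():
    ref = _ref_with_diameters([4.2, 5.0, 7.1])
    view = nv.select_subset(ref, nv.SubsetSpec(3.0, "all"))
    assert view.n_targets == 3
    assert len(view.ignore) == len(ref.exclusion_list) == 0


def test_min_diameter_threshold_is_inclusive():
    ref = _ref_with_diameters([4.2, 5.0, 7.1])
    view = nv.select_subset(ref, nv.SubsetSpec(5.0, "all"))
    assert view.n_targets == 2
    assert len(view.ignore) == 1


def test_perifissural_benign_is_not_actionable():
    ref = _ref_with_diameters([6.0, 6.0], ["perifissural", "solid"])
    view = nv.select_subset(ref, nv.SubsetSpec(3.0, "actionable_benign"))
    assert view.n_targets == 1
    assert view.targets[0].nodule_type == "solid"


def test_actionable_count_matches_definition(rng):
    panel, manifest = _random_panel(rng)
    ref = nv.build_reference_standard(panel, manifest)
    expected = sum(
        n.malignancy == "benign" and n.equivalent_diameter >= 5
        and n.nodule_type not in ("calcified", "perifissural")
        for n in ref.nodules
    )
    assert sum(n.actionable for n in ref.nodules) == expected


# ---------------------------------------------------------------------------
# Leave-one-out
# ---------------------------------------------------------------------------

def test_leave_one_out_keeps_full_agreement_nodules():
    panel = _panel([(f"r{i + 1}", (0, 0, 0), 8) for i in range(5)])
    loo = nv.leave_one_out_reference(panel, MANIFEST, [], "r1")
    assert len(loo.nodules) == 1 and loo.nodules[0].agreement == 4


def test_leave_one_out_drops_benign_at_the_margin():
    panel = _panel([("r1", (0, 0, 0), 8), ("r2", (0, 0, 0), 8),
                    ("r3", (0, 0, 0), 8)])
    loo = nv.leave_one_out_reference(panel, MANIFEST, [], "r1")
    assert loo.nodules == []
    assert loo.exclusion_list[0].reason == "minority"


def test_leave_one_out_retains_registry_linked_malignancy():
    panel = _panel([("r2", (0, 0, 0), 8), ("r4", (0, 0, 0), 8)])
    reg = [nv.RegistryRecord("s1", (0, 0, 0), 8.0, "metastasis")]
    loo = nv.leave_one_out_reference(panel, MANIFEST, reg, "r2")
    [n] = loo.nodules
    assert n.malignancy == "metastasis"


def test_leave_one_out_requires_enough_readers():
    panel = {f"r{i + 1}": [] for i in range(3)}
    with pytest.raises(ValueError, match="readers"):
        nv.leave_one_out_reference(panel, MANIFEST, [], "r1")
    with pytest.raises(KeyError):
        nv.leave_one_out_reference({f"r{i}": [] for i in range(5)},
                                   MANIFEST, [], "ghost")
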