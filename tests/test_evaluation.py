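"""Fold construction, metrics, curves and the evaluation designs."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from kmst import (
    DEFAULT_CLASS_ORDER,
    MstParams,
    ParameterError,
    SampleMetadata,
    ShapeError,
    build_matrix_from_kmer_sets,
    composition_percentages,
    compute_metrics,
    cross_validate,
    curves,
    diversity_class,
    leave_one_out,
    make_group_stratified_folds,
)
from tests.conftest import distinct_kmer_blocks


def _grid_metadata(n_groups=10, classes=DEFAULT_CLASS_ORDER):
    """n_groups groups x one sample of every class: perfectly decomposable."""
    meta = []
    for g in range(n_groups):
        for c in classes:
            meta.append(SampleMetadata(f"g{g}-{c}", c, f"g{g}"))
    return meta


def test_folds_on_perfectly_decomposable_instance():
    meta = _grid_metadata(10)
    folds = make_group_stratified_folds(meta, n_folds=5, seed=0)
    for f in range(5):
        members = folds.members(f)
        assert len(members) == 8
        labels = Counter(
            m.label for m in meta if m.sample_id in set(members)
        )
        assert set(labels.values()) == {2}  # exact 25/25/25/25 split


def test_folds_never_split_a_group(rng):
    meta = []
    for g in range(17):
        size = int(rng.integers(1, 6))
        for i in range(size):
            label = str(rng.choice(DEFAULT_CLASS_ORDER))
            meta.append(SampleMetadata(f"g{g}-s{i}", label, f"g{g}"))
    for seed in (0, 1, 2):
        folds = make_group_stratified_folds(meta, n_folds=4, seed=seed)
        fold_of_group = {}
        for m in meta:
            f = folds.fold_of[m.sample_id]
            assert fold_of_group.setdefault(m.group, f) == f
        assert set(folds.fold_of) == {m.sample_id for m in meta}
    # determinism: same seed twice gives the same assignment
    a = make_group_stratified_folds(meta, n_folds=4, seed=7).fold_of
    b = make_group_stratified_folds(meta, n_folds=4, seed=7).fold_of
    assert a == b


def test_fold_degenerate_cases():
    meta = _grid_metadata(3)
    single = make_group_stratified_folds(meta, n_folds=1, seed=0)
    assert set(single.fold_of.values()) == {0}
    with pytest.raises(ParameterError):
        make_group_stratified_folds(meta, n_folds=4, seed=0)


def test_metrics_hand_computed_confusion():
    report = compute_metrics(
        ["A", "A", "B", "B"], ["A", "B", "B", "B"], class_order=("A", "B")
    )
    assert report.accuracy == pytest.approx(3 / 4)
    assert report.per_class["A"]["precision"] == pytest.approx(1.0)
    assert report.per_class["B"]["precision"] == pytest.approx(2 / 3)
    assert report.precision == pytest.approx(5 / 6)
    assert report.per_class["A"]["recall"] == pytest.approx(1 / 2)
    assert report.per_class["B"]["recall"] == pytest.approx(1.0)
    assert report.recall == pytest.approx(3 / 4)
    assert report.confusion.tolist() == [[1, 1], [0, 2]]


def test_metrics_edge_cases():
    perfect = compute_metrics(["A", "B"], ["A", "B"], class_order=("A", "B"))
    assert (
        perfect.accuracy,
        perfect.precision,
        perfect.recall,
        perfect.f1,
    ) == (1.0, 1.0, 1.0, 1.0)
    wrong = compute_metrics(["A", "B"], ["B", "A"], class_order=("A", "B"))
    assert wrong.accuracy == 0.0 and wrong.recall == 0.0
    unassigned = compute_metrics(
        ["A", "B"], ["unassigned", "B"], class_order=("A", "B")
    )
    assert unassigned.accuracy == pytest.approx(0.5)
    assert unassigned.n_unassigned == 1
    with pytest.raises(ShapeError):
        compute_metrics(["A"], ["A", "B"], class_order=("A", "B"))


def test_curves_separation_and_monotonicity():
    y = ["A"] * 5 + ["B"] * 5
    scores = [np.array([0.9, 0.1]) for _ in range(5)] + [
        np.array([0.1, 0.9]) for _ in range(5)
    ]
    cs = curves(y, scores, class_order=("A", "B"))
    assert cs.auroc["A"] == pytest.approx(1.0)
    assert cs.auroc["B"] == pytest.approx(1.0)
    assert cs.macro_auroc == pytest.approx(1.0)
    for fpr, tpr, _ in cs.roc.values():
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert (np.diff(tpr) >= 0).all()


def test_curves_random_scores_auroc_near_half():
    null_rng = np.random.default_rng(0)
    n = 1000
    y = [str(null_rng.choice(("A", "B"))) for _ in range(n)]
    scores = [null_rng.random(2) for _ in range(n)]
    cs = curves(y, scores, class_order=("A", "B"))
    assert cs.auroc["A"] == pytest.approx(0.5, abs=0.05)
    assert cs.auroc["B"] == pytest.approx(0.5, abs=0.05)


def test_curves_skip_absent_class():
    y = ["A", "A"]
    scores = [np.array([0.7, 0.3]), np.array([0.6, 0.4])]
    cs = curves(y, scores, class_order=("A", "B"))
    assert cs.skipped_classes == ["B"]
    assert "B" not in cs.auroc


@pytest.mark.parametrize(
    "p_max, expected",
    [
        (0.80, "mono-source"),
        (0.75, "multi-source"),  # strict inequality at the threshold
        (0.20, "multi-source"),
    ],
)
def test_diversity_threshold(p_max, expected):
    rest = (1 - p_max) / 3
    assert diversity_class(np.array([p_max, rest, rest, rest])) == expected


def test_diversity_null_proportions():
    with pytest.warns(UserWarning):
        assert diversity_class(None) == "multi-source"


def test_composition_percentages():
    pcts, total = composition_percentages({"a": 1, "b": 3})
    assert total == 4 and pcts == {"a": 25.0, "b": 75.0}


def test_leave_one_out_on_disjoint_pools(disjoint_pool_collection):
    matrix, metadata = disjoint_pool_collection
    results, report, curveset = leave_one_out(
        matrix, metadata, MstParams(k=matrix.k)
    )
    assert len(results) == len(metadata)
    assert report.accuracy == 1.0
    assert report.f1 == 1.0
    assert all(cs == pytest.approx(1.0) for cs in curveset.auroc.values())


def test_leave_one_out_excludes_the_sink_from_sources():
    # every sample is unique: if the sink leaked into the sources it would
    # match itself perfectly instead of being unassigned
    blocks = distinct_kmer_blocks(4, 6, k=7)
    labels = ["aOral", "mOral", "skin", "sediment/soil"]
    samples = [
        (SampleMetadata(f"s{i}", labels[i], f"g{i}"), block)
        for i, block in enumerate(blocks)
    ]
    matrix, metadata = build_matrix_from_kmer_sets(samples, min_recurrence=1)
    results, report, _ = leave_one_out(matrix, metadata, MstParams(k=7))
    assert all(r.predicted_label == "unassigned" for r in results)
    assert report.accuracy == 0.0


def test_label_randomization_drops_accuracy_to_chance(
    disjoint_pool_collection, rng
):
    matrix, metadata = disjoint_pool_collection
    hits = trials = 0
    for _ in range(50):
        shuffled = [
            SampleMetadata(m.sample_id, str(rng.choice(DEFAULT_CLASS_ORDER)), m.group)
            for m in metadata
        ]
        _, report, _ = leave_one_out(matrix, shuffled, MstParams(k=matrix.k))
        hits += report.accuracy * len(shuffled)
        trials += len(shuffled)
    # prediction copies the class partner's random label: 1/|C| chance
    assert hits / trials == pytest.approx(0.25, abs=0.12)


def _group_structured_collection():
    """Groups carry private k-mer content on top of weaker class content,
    plus cross-class confusion, so within-group matches inflate LOO."""
    classes = DEFAULT_CLASS_ORDER
    blocks = distinct_kmer_blocks(12, 24, k=9)
    class_blocks = [set(sorted(b)[:4]) for b in blocks[:4]]
    group_blocks = blocks[4:]
    samples = []
    gi = 0
    for c, (label, cpool) in enumerate(zip(classes, class_blocks)):
        confusion = class_blocks[(c + 1) % 4]  # shared with the next class
        for g in range(2):
            gpool = group_blocks[gi]
            gi += 1
            for r in range(2):
                meta = SampleMetadata(f"{label}-g{g}-r{r}", label, f"{label}-g{g}")
                samples.append((meta, set(cpool) | set(gpool) | set(confusion)))
    return build_matrix_from_kmer_sets(samples, min_recurrence=2)


def test_cross_validation_is_not_more_optimistic_than_loo():
    matrix, metadata = _group_structured_collection()
    params = MstParams(k=matrix.k)
    _, loo_report, _ = leave_one_out(matrix, metadata, params)
    cv = cross_validate(matrix, metadata, n_folds=4, seed=0, params=params)
    assert len(cv.per_fold) == 4
    assert cv.pooled.accuracy <= loo_report.accuracy + 1e-9
    # sinks of a fold never sit among that fold's sources
    for f in range(4):
        sink_ids = set(cv.folds.members(f))
        for sid in sink_ids:
            assert cv.folds.groups[sid] == metadata[
                [m.sample_id for m in metadata].index(sid)
            ].group


def test_cross_validation_respects_group_boundaries(disjoint_pool_collection):
    matrix, metadata = disjoint_pool_collection
    cv = cross_validate(
        matrix, metadata, n_folds=2, seed=1, params=MstParams(k=matrix.k)
    )
    assert len(cv.results) == len(metadata)
    for sid, fold in cv.folds.fold_of.items():
        group = cv.folds.groups[sid]
        same_group = [s for s, g in cv.folds.groups.items() if g == group]
        assert {cv.folds.fold_of[s] for s in same_group} == {fold}
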