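"""Experimental designs and metrics for benchmarking the estimator.

Two designs are provided: leave-one-out (every sample in turn is the sink,
all remaining samples are the sources) and group-stratified k-fold
cross-validation, where samples from the same group (a BioProject-like
sequencing-initiative accession) never appear in two different folds, so a
sink is never classified against sources from its own initiative.

Hard labels are scored with accuracy plus macro-averaged one-vs-rest
precision, recall and F1; proportion outputs additionally yield per-class
ROC and precision-recall curves.  Samples whose top proportion exceeds 75%
are categorized as mono-source, the rest as multi-source.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    auc,
    balanced_accuracy_score,
    confusion_matrix,
    precision_recall_curve,
    precision_recall_fscore_support,
    roc_curve,
)

from .errors import ParameterError, ShapeError
from .kmer_core import SampleKmerSet
from .matrix_build import DEFAULT_CLASS_ORDER, KmerMatrix, SampleMetadata
from .mst_engine import MstParams, MstResult, run_mst_from_kmers

logger = logging.getLogger(__name__)

MONO_SOURCE_THRESHOLD = 0.75


# --- fold construction ---------------------------------------------------


@dataclass
class FoldAssignment:
    """Sample -> fold mapping honouring group non-overlap exactly."""

    n_folds: int
    fold_of: dict[str, int]
    groups: dict[str, str]

    def members(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]


def make_group_stratified_folds(
    metadata: Sequence[SampleMetadata],
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Greedy group-stratified splitter.

    Groups (never split) are placed largest-first into the fold whose
    per-class counts are furthest below the ideal per-fold share, which
    simultaneously balances fold sizes and class proportions.  Deterministic
    for a given seed (the seed only shuffles ties in the processing order).
    """
    if n_folds < 1:
        raise ParameterError("n_folds must be >= 1")
    classes = sorted({m.label for m in metadata})
    group_counts: dict[str, np.ndarray] = {}
    for m in metadata:
        vec = group_counts.setdefault(m.group, np.zeros(len(classes), dtype=float))
        vec[classes.index(m.label)] += 1
    if len(group_counts) < n_folds:
        raise ParameterError(
            f"{len(group_counts)} groups cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    names = sorted(group_counts)
    rng.shuffle(names)
    names.sort(key=lambda g: -group_counts[g].sum())  # stable: ties keep shuffle
    total = sum(group_counts.values())
    target = total / n_folds
    fold_counts = np.zeros((n_folds, len(classes)), dtype=float)
    fold_of_group: dict[str, int] = {}
    for g in names:
        # marginal increase in squared deviation from the ideal per-fold
        # class counts: prefers the fold most deficient in g's classes;
        # ties go to the smallest fold, then the lowest index
        costs = ((fold_counts + group_counts[g] - target) ** 2).sum(axis=1) - (
            (fold_counts - target) ** 2
        ).sum(axis=1)
        sizes = fold_counts.sum(axis=1)
        best = min(range(n_folds), key=lambda f: (costs[f], sizes[f], f))
        fold_of_group[g] = best
        fold_counts[best] += group_counts[g]
    fold_of = {m.sample_id: fold_of_group[m.group] for m in metadata}
    assignment = FoldAssignment(
        n_folds=n_folds,
        fold_of=fold_of,
        groups={m.sample_id: m.group for m in metadata},
    )
    for f in range(n_folds):
        if not assignment.members(f):
            logger.warning("fold %d is empty", f)
    return assignment


# --- metrics -------------------------------------------------------------


@dataclass
class MetricsReport:
    """Hard-label classification metrics.

    ``accuracy`` is the global fraction of exact matches; precision, recall
    and F1 are one-vs-rest per class, then averaged (macro by default).
    Predictions of "unassigned" count as wrong for every class.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray
    class_order: tuple[str, ...]
    balanced_accuracy: float = float("nan")
    n_unassigned: int = 0


def compute_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
    average: str = "macro",
) -> MetricsReport:
    """Score hard labels against truth.

    ``average`` may be "macro" (unweighted class mean, the default) or
    "weighted" (support-weighted); classes with no predicted positives get
    precision 0.
    """
    if len(y_true) != len(y_pred):
        raise ShapeError(f"{len(y_true)} truths vs {len(y_pred)} predictions")
    labels = list(class_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn's zero-division chatter
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average=None, zero_division=0
        )
        avg_prec, avg_rec, avg_f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average=average, zero_division=0
        )
        balanced = balanced_accuracy_score(y_true, y_pred)
    per_class = {
        c: {
            "precision": float(prec[j]),
            "recall": float(rec[j]),
            "f1": float(f1[j]),
            "support": int(support[j]),
        }
        for j, c in enumerate(labels)
    }
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(avg_prec),
        recall=float(avg_rec),
        f1=float(avg_f1),
        per_class=per_class,
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
        class_order=tuple(labels),
        balanced_accuracy=float(balanced),
        n_unassigned=sum(1 for p in y_pred if p not in labels),
    )


@dataclass
class CurveSet:
    """Per-class ROC/PR curve points plus a macro-averaged ROC."""

    roc: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    pr: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    auroc: dict[str, float]
    aupr: dict[str, float]
    macro_fpr: np.ndarray
    macro_tpr: np.ndarray
    macro_auroc: float
    skipped_classes: list[str] = field(default_factory=list)


def curves(
    y_true: Sequence[str],
    scores: Sequence[np.ndarray | None],
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
    grid_points: int = 101,
) -> CurveSet:
    """One-vs-rest ROC and precision-recall curves from proportion scores.

    Each sample is scored for class c by its estimated proportion p'[c];
    sinks with undefined proportions score 0 for every class.  The macro
    ROC averages per-class TPR on a fixed FPR grid.
    """
    class_order = tuple(class_order)
    n = len(y_true)
    score_mat = np.zeros((n, len(class_order)), dtype=float)
    for i, s in enumerate(scores):
        if s is not None:
            score_mat[i] = np.asarray(s, dtype=float)
    roc: dict[str, tuple] = {}
    pr: dict[str, tuple] = {}
    auroc: dict[str, float] = {}
    aupr: dict[str, float] = {}
    skipped: list[str] = []
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = []
    for j, c in enumerate(class_order):
        truth = np.array([1 if t == c else 0 for t in y_true])
        if truth.sum() == 0:
            logger.warning("class %s absent from truth; curve skipped", c)
            skipped.append(c)
            continue
        fpr, tpr, thr = roc_curve(truth, score_mat[:, j])
        p, r, pthr = precision_recall_curve(truth, score_mat[:, j])
        roc[c] = (fpr, tpr, thr)
        pr[c] = (p, r, pthr)
        auroc[c] = float(auc(fpr, tpr))
        aupr[c] = float(auc(r, p))
        tprs.append(np.interp(grid, fpr, tpr))
    macro_tpr = np.mean(tprs, axis=0) if tprs else np.zeros_like(grid)
    return CurveSet(
        roc=roc,
        pr=pr,
        auroc=auroc,
        aupr=aupr,
        macro_fpr=grid,
        macro_tpr=macro_tpr,
        macro_auroc=float(np.trapezoid(macro_tpr, grid)),
        skipped_classes=skipped,
    )


# --- experimental designs ------------------------------------------------


def _column_kmer_set(
    matrix: KmerMatrix, column: int, min_abundance: int
) -> SampleKmerSet:
    """Reconstruct a sample's (matrix-restricted) k-mer set from its column."""
    present = frozenset(
        km for km, bit in zip(matrix.kmers, matrix.cells[:, column]) if bit
    )
    return SampleKmerSet(
        sample_id=matrix.sample_ids[column],
        kmers=present,
        counts={km: min_abundance for km in present},
        k=matrix.k,
        min_abundance=min_abundance,
    )


def _drop_columns(
    matrix: KmerMatrix, metadata: Sequence[SampleMetadata], drop: set[int]
) -> tuple[KmerMatrix, list[SampleMetadata]]:
    keep = [j for j in range(matrix.n_samples) if j not in drop]
    sub = KmerMatrix(
        kmers=matrix.kmers,
        sample_ids=[matrix.sample_ids[j] for j in keep],
        cells=matrix.cells[:, keep],
        k=matrix.k,
        partition_id=matrix.partition_id,
        provenance=matrix.provenance,
    )
    return sub, [metadata[j] for j in keep]


def leave_one_out(
    matrix: KmerMatrix,
    metadata: Sequence[SampleMetadata],
    params: MstParams = MstParams(),
) -> tuple[list[MstResult], MetricsReport, CurveSet]:
    """Use each sample as a sink against all remaining samples as sources."""
    if matrix.n_samples < 2:
        raise ParameterError("leave-one-out needs at least 2 samples")
    results: list[MstResult] = []
    for s in range(matrix.n_samples):
        sink_set = _column_kmer_set(matrix, s, params.min_abundance)
        sources, source_meta = _drop_columns(matrix, metadata, {s})
        assert matrix.sample_ids[s] not in sources.sample_ids
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results.append(
                run_mst_from_kmers(sink_set, sources, source_meta, params)
            )
    y_true = [m.label for m in metadata]
    y_pred = [r.predicted_label for r in results]
    report = compute_metrics(y_true, y_pred, params.class_order)
    curveset = curves(y_true, [r.proportions for r in results], params.class_order)
    return results, report, curveset


@dataclass
class CrossValReport:
    """Per-fold and pooled scores of a group-stratified cross-validation."""

    folds: FoldAssignment
    per_fold: list[MetricsReport]
    pooled: MetricsReport
    results: list[MstResult]
    pooled_curves: CurveSet


def cross_validate(
    matrix: KmerMatrix,
    metadata: Sequence[SampleMetadata],
    n_folds: int = 5,
    seed: int = 0,
    params: MstParams = MstParams(),
) -> CrossValReport:
    """Group-stratified k-fold: fold members are sinks, the rest sources."""
    assignment = make_group_stratified_folds(metadata, n_folds, seed)
    index_of = {sid: j for j, sid in enumerate(matrix.sample_ids)}
    all_results: list[MstResult] = []
    all_true: list[str] = []
    per_fold: list[MetricsReport] = []
    for f in range(n_folds):
        sink_ids = assignment.members(f)
        if not sink_ids:
            logger.warning("fold %d is empty; no metrics for it", f)
            continue
        sink_cols = {index_of[s] for s in sink_ids}
        sources, source_meta = _drop_columns(matrix, metadata, sink_cols)
        source_labels = {m.label for m in source_meta}
        for c in params.class_order:
            if c not in source_labels:
                logger.warning("fold %d has no source of class %s", f, c)
        fold_results = []
        for sid in sink_ids:
            sink_set = _column_kmer_set(matrix, index_of[sid], params.min_abundance)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold_results.append(
                    run_mst_from_kmers(sink_set, sources, source_meta, params)
                )
        fold_true = [metadata[index_of[s]].label for s in sink_ids]
        per_fold.append(
            compute_metrics(
                fold_true,
                [r.predicted_label for r in fold_results],
                params.class_order,
            )
        )
        all_results.extend(fold_results)
        all_true.extend(fold_true)
    pooled = compute_metrics(
        all_true, [r.predicted_label for r in all_results], params.class_order
    )
    pooled_curves = curves(
        all_true, [r.proportions for r in all_results], params.class_order
    )
    return CrossValReport(
        folds=assignment,
        per_fold=per_fold,
        pooled=pooled,
        results=all_results,
        pooled_curves=pooled_curves,
    )


# --- sample categorization ----------------------------------------------


def diversity_class(
    result: MstResult | np.ndarray | None,
    threshold: float = MONO_SOURCE_THRESHOLD,
) -> str:
    """Mono-source iff the top proportion strictly exceeds the threshold.

    The 75% default splits each class at its upper quartile of estimated
    purity: mono-source samples are dominated by one environment, the rest
    are of mixed origin.
    """
    p = result.proportions if isinstance(result, MstResult) else result
    if p is None:
        warnings.warn(
            "null proportions categorized as multi-source", UserWarning, stacklevel=2
        )
        return "multi-source"
    return "mono-source" if float(np.max(p)) > threshold else "multi-source"


def composition_percentages(
    counts: Mapping[str, int], ndigits: int = 1
) -> tuple[dict[str, float], int]:
    """Per-class percentages (rounded) and the total of a labelled count table."""
    total = sum(counts.values())
    if total == 0:
        raise ParameterError("empty count table")
    return {c: round(100.0 * n / total, ndigits) for c, n in counts.items()}, total
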