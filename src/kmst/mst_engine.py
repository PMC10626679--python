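"""Core source-tracking estimator.

Given a binary source matrix ``M_s`` (K k-mers x L-1 sources), a one-hot
label matrix ``H`` ((L-1) x |C|) and a sink presence vector ``m``, the
per-environment "ball counts" are

    w = m^T . M_s . H

i.e. every (k-mer, source) pair with the k-mer present in both the sink and
that source drops one ball into the bin of the source's environment label.
Counts are normalized to proportions ``p' = w / sum(w)``, which sum to 1
(100%) whenever the sink shares at least one k-mer with the sources.  The
hard label is the argmax class; the unknown fraction is the share of sink
k-mers absent from every source and is reported separately, outside the
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    NoMatchWarning,
    ParameterError,
    ShapeError,
)
from .kmer_core import SampleKmerSet, extract_present_kmers
from .matrix_build import (
    DEFAULT_CLASS_ORDER,
    KmerMatrix,
    OneHotMatrix,
    SampleMetadata,
    encode_one_hot,
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SinkVector:
    """Presence vector of a sink aligned to a source matrix's row order.

    Sink k-mers absent from the matrix rows are not represented in ``bits``;
    they are only tracked through ``n_sink_kmers_total`` (the sink's k-mer
    count after abundance filtering, before intersection with the rows).
    """

    sink_id: str
    bits: np.ndarray  # uint8, length K
    n_sink_kmers_total: int


@dataclass
class MstResult:
    """Estimated composition of one sink."""

    sink_id: str
    w: np.ndarray  # int64 ball counts, length |C|
    proportions: np.ndarray | None  # fractions summing to 1, or None
    unknown_fraction: float | None
    predicted_label: str
    tie: bool
    n_matched_kmers: int
    n_sink_kmers_total: int
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER

    @property
    def percentages(self) -> np.ndarray | None:
        """Proportions on the 0-100 scale, or None when undefined."""
        return None if self.proportions is None else self.proportions * 100.0


def vectorize_sink(sink_kmers: SampleKmerSet, matrix: KmerMatrix) -> SinkVector:
    """Project a sink's k-mer set onto the matrix row index."""
    if sink_kmers.k != matrix.k:
        raise ParameterError(
            f"sink k={sink_kmers.k} does not match matrix k={matrix.k}"
        )
    present = sink_kmers.kmers
    bits = np.fromiter(
        (1 if km in present else 0 for km in matrix.kmers),
        dtype=np.uint8,
        count=matrix.n_kmers,
    )
    return SinkVector(
        sink_id=sink_kmers.sample_id,
        bits=bits,
        n_sink_kmers_total=len(present),
    )


def count_environment_balls(
    sink: SinkVector | np.ndarray,
    sources: KmerMatrix | np.ndarray,
    one_hot: OneHotMatrix | np.ndarray,
) -> np.ndarray:
    """Eq.-style ball counting: w = m^T . M_s . H (exact integer counts)."""
    bits = sink.bits if isinstance(sink, SinkVector) else np.asarray(sink)
    cells = sources.cells if isinstance(sources, KmerMatrix) else np.asarray(sources)
    h = one_hot.rows if isinstance(one_hot, OneHotMatrix) else np.asarray(one_hot)
    if bits.shape[0] != cells.shape[0]:
        raise ShapeError(
            f"sink length {bits.shape[0]} != matrix rows {cells.shape[0]}"
        )
    if cells.shape[1] != h.shape[0]:
        raise ShapeError(
            f"matrix columns {cells.shape[1]} != one-hot rows {h.shape[0]}"
        )
    return (
        bits.astype(np.int64) @ cells.astype(np.int64) @ h.astype(np.int64)
    )


def normalize_proportions(w: np.ndarray) -> np.ndarray | None:
    """Turn ball counts into proportions; None (with a warning) if all zero."""
    w = np.asarray(w, dtype=np.float64)
    total = w.sum()
    if total == 0:
        warnings.warn(
            "sink shares no k-mer with any source; proportions undefined",
            NoMatchWarning,
            stacklevel=2,
        )
        return None
    return w / total


def predict_label(
    proportions: np.ndarray | None,
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> tuple[str, bool]:
    """Hard label = class with the highest proportion.

    Ties are broken by class order (earliest wins) and flagged; a null
    proportion vector yields ``("unassigned", False)``.
    """
    if proportions is None:
        return UNASSIGNED, False
    p = np.asarray(proportions, dtype=np.float64)
    best = p.max()
    winners = np.flatnonzero(p == best)
    return tuple(class_order)[winners[0]], winners.size > 1


def unknown_fraction(sink_kmers: SampleKmerSet, sources: KmerMatrix) -> float:
    """Fraction of sink k-mers present in no source at all.

    A sink k-mer is unknown when it is absent from the matrix row index or
    its row is all-zero across the source columns.
    """
    if not sink_kmers.kmers:
        raise EmptyInputError("sink has no k-mers after abundance filtering")
    covered_rows = {
        km
        for km, row_any in zip(sources.kmers, sources.cells.any(axis=1))
        if row_any
    }
    n_unknown = sum(1 for km in sink_kmers.kmers if km not in covered_rows)
    return n_unknown / len(sink_kmers.kmers)


@dataclass(frozen=True)
class MstParams:
    """Knobs of one estimator run."""

    k: int = 31
    min_abundance: int = 2
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER
    compute_unknown: bool = True


def run_mst_from_kmers(
    sink_kmers: SampleKmerSet,
    sources: KmerMatrix,
    metadata: Sequence[SampleMetadata],
    params: MstParams = MstParams(),
) -> MstResult:
    """Estimate composition of an already-extracted sink k-mer set."""
    sink = vectorize_sink(sink_kmers, sources)
    one_hot = encode_one_hot(metadata, params.class_order)
    w = count_environment_balls(sink, sources, one_hot)
    proportions = normalize_proportions(w)
    label, tie = predict_label(proportions, params.class_order)
    unknown = (
        unknown_fraction(sink_kmers, sources)
        if params.compute_unknown and sink_kmers.kmers
        else None
    )
    return MstResult(
        sink_id=sink_kmers.sample_id,
        w=w,
        proportions=proportions,
        unknown_fraction=unknown,
        predicted_label=label,
        tie=tie,
        n_matched_kmers=int(sink.bits.sum()),
        n_sink_kmers_total=sink.n_sink_kmers_total,
        class_order=tuple(params.class_order),
    )


def run_mst(
    sink_reads: Iterable[str],
    sources: KmerMatrix,
    metadata: Sequence[SampleMetadata],
    params: MstParams = MstParams(),
    sink_id: str = "sink",
) -> MstResult:
    """Full single-sink pipeline: reads -> k-mers -> vector -> proportions."""
    if params.k != sources.k:
        raise ParameterError(
            f"params.k={params.k} does not match matrix k={sources.k}"
        )
    sink_kmers = extract_present_kmers(
        sink_reads, k=params.k, min_abundance=params.min_abundance, sample_id=sink_id
    )
    return run_mst_from_kmers(sink_kmers, sources, metadata, params)
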