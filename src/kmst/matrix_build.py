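"""Assembly, filtering, one-hot label encoding and TSV (de)serialization of
the binary source matrix.

The source matrix ``M`` has one row per canonical k-mer (lexicographically
sorted) and one column per sample; a cell is 1 iff the k-mer is present in
the sample after within-sample abundance filtering.  Two cross-sample steps
follow: k-mers are optionally restricted to a single hash partition, and
rows seen in fewer than ``min_recurrence`` samples are dropped (default 3),
keeping only recurrent patterns that help discriminate environments.

Sample labels come from a fixed ordered class set, by default
``("aOral", "mOral", "skin", "sediment/soil")`` — ancient oral, modern
oral, skin and sediment/soil environments — and are projected to a one-hot
matrix ``H`` with H[i, j] = 1 iff sample i carries label j.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import kmer_core
from .errors import (
    DuplicateSampleError,
    FormatError,
    MetadataError,
    ParameterError,
    UnknownClassError,
)
from .kmer_core import SampleKmerSet

logger = logging.getLogger(__name__)

DEFAULT_CLASS_ORDER: tuple[str, ...] = ("aOral", "mOral", "skin", "sediment/soil")
DEFAULT_MIN_RECURRENCE = 3


@dataclass(frozen=True)
class SampleMetadata:
    """Label and group annotation for one sample column.

    ``group`` plays the role of a BioProject-like accession grouping and is
    the unit kept intact by group-stratified cross-validation.
    """

    sample_id: str
    label: str
    group: str

    def __post_init__(self) -> None:
        if not self.label:
            raise MetadataError(f"sample {self.sample_id!r} has no label")
        if not self.group:
            raise MetadataError(f"sample {self.sample_id!r} has no group")


@dataclass
class KmerMatrix:
    """Binary presence/absence matrix: K k-mer rows x N sample columns."""

    kmers: list[str]
    sample_ids: list[str]
    cells: np.ndarray  # uint8, shape (K, N), values in {0, 1}
    k: int = kmer_core.DEFAULT_K
    partition_id: int | str = "all"
    provenance: dict = field(default_factory=dict)

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.cells[:, self.sample_ids.index(sample_id)]


@dataclass
class OneHotMatrix:
    """One-hot projection of source labels onto the ordered class set."""

    class_order: tuple[str, ...]
    rows: np.ndarray  # uint8, shape (n_sources, |C|)


def build_source_matrix(
    samples: Sequence[tuple[SampleMetadata, Iterable[str]]],
    k: int = kmer_core.DEFAULT_K,
    min_abundance: int = kmer_core.DEFAULT_MIN_ABUNDANCE,
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
    num_partitions: int = 1,
    selected_partition: int | str = "all",
    partition_salt: int = 0,
) -> tuple[KmerMatrix, list[SampleMetadata]]:
    """Build the labelled source matrix from per-sample reads.

    Each sample's reads are reduced to abundance-filtered canonical k-mers,
    then the matrix rows are the k-mers that fall into the selected
    partition (or any, when ``"all"``) and occur in at least
    ``min_recurrence`` samples.  Columns keep the input sample order.
    """
    kmer_sets = [
        kmer_core.extract_present_kmers(
            reads, k=k, min_abundance=min_abundance, sample_id=meta.sample_id
        )
        for meta, reads in samples
    ]
    metadata = [meta for meta, _ in samples]
    return build_matrix_from_kmer_sets(
        list(zip(metadata, kmer_sets)),
        min_recurrence=min_recurrence,
        num_partitions=num_partitions,
        selected_partition=selected_partition,
        partition_salt=partition_salt,
        min_abundance=min_abundance,
    )


def build_matrix_from_kmer_sets(
    samples: Sequence[tuple[SampleMetadata, SampleKmerSet | Iterable[str]]],
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
    num_partitions: int = 1,
    selected_partition: int | str = "all",
    partition_salt: int = 0,
    min_abundance: int | None = None,
) -> tuple[KmerMatrix, list[SampleMetadata]]:
    """Assemble the matrix from already-extracted per-sample k-mer sets."""
    if len(samples) < 2:
        raise ParameterError("need at least 2 samples to build a source matrix")
    if min_recurrence < 1:
        raise ParameterError("min_recurrence must be >= 1")
    metadata: list[SampleMetadata] = []
    seen: set[str] = set()
    sets: list[frozenset[str]] = []
    k = None
    for meta, km in samples:
        if meta.sample_id in seen:
            raise DuplicateSampleError(f"duplicate sample id {meta.sample_id!r}")
        seen.add(meta.sample_id)
        metadata.append(meta)
        if isinstance(km, SampleKmerSet):
            if k is not None and km.k != k:
                raise ParameterError("samples disagree on k")
            k = km.k
            sets.append(km.kmers)
        else:
            sets.append(frozenset(km))
    if k is None:
        lengths = {len(x) for s in sets for x in s}
        k = lengths.pop() if len(lengths) == 1 else kmer_core.DEFAULT_K

    universe = sorted(set().union(*sets))
    if selected_partition != "all":
        universe = [
            km
            for km in universe
            if kmer_core.assign_partition(km, num_partitions, partition_salt)
            == selected_partition
        ]
    index = {km: i for i, km in enumerate(universe)}
    cells = np.zeros((len(universe), len(sets)), dtype=np.uint8)
    for j, kmset in enumerate(sets):
        rows = [index[km] for km in kmset if km in index]
        cells[rows, j] = 1
    keep = cells.sum(axis=1) >= min_recurrence
    kmers = [km for km, flag in zip(universe, keep) if flag]
    cells = cells[keep]

    for j, meta in enumerate(metadata):
        if cells.shape[0] and cells[:, j].sum() == 0 or cells.shape[0] == 0:
            logger.warning(
                "sample %s has no k-mer surviving the filters; keeping an "
                "all-zero column",
                meta.sample_id,
            )
    matrix = KmerMatrix(
        kmers=kmers,
        sample_ids=[m.sample_id for m in metadata],
        cells=cells,
        k=k,
        partition_id=selected_partition,
        provenance={
            "min_abundance": min_abundance,
            "min_recurrence": min_recurrence,
            "num_partitions": num_partitions,
            "partition_salt": partition_salt,
        },
    )
    return matrix, metadata


def encode_one_hot(
    metadata: Sequence[SampleMetadata],
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> OneHotMatrix:
    """One-hot encode source labels: H[i, j] = 1 iff label_i == class_j."""
    class_order = tuple(class_order)
    col = {c: j for j, c in enumerate(class_order)}
    rows = np.zeros((len(metadata), len(class_order)), dtype=np.uint8)
    for i, meta in enumerate(metadata):
        if meta.label not in col:
            raise UnknownClassError(
                f"label {meta.label!r} of sample {meta.sample_id!r} is not in "
                f"the class order {class_order}"
            )
        rows[i, col[meta.label]] = 1
    return OneHotMatrix(class_order=class_order, rows=rows)


# --- serialization -------------------------------------------------------
#
# Dialect: <path> is a TSV whose header line is "#kmer\t<id1>\t<id2>..."
# followed by one row per k-mer with literal 0/1 cells, LF line endings;
# <path>.meta.tsv carries sample_id/label/group; <path>.json carries k and
# filter provenance.  The round trip is bit-exact.


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.tsv")


def _json_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def serialize_matrix(
    matrix: KmerMatrix, metadata: Sequence[SampleMetadata], path: str | Path
) -> None:
    """Write the matrix, its sample metadata and its provenance sidecars."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("#kmer\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, km in enumerate(matrix.kmers):
            fh.write(km + "\t" + "\t".join(map(str, matrix.cells[i])) + "\n")
    with open(_meta_path(path), "w", newline="\n") as fh:
        fh.write("sample_id\tlabel\tgroup\n")
        for meta in metadata:
            fh.write(f"{meta.sample_id}\t{meta.label}\t{meta.group}\n")
    sidecar = {
        "k": matrix.k,
        "partition_id": matrix.partition_id,
        "provenance": matrix.provenance,
    }
    with open(_json_path(path), "w", newline="\n") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")


def deserialize_matrix(
    path: str | Path,
) -> tuple[KmerMatrix, list[SampleMetadata]]:
    """Read back a matrix written by :func:`serialize_matrix`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if not fields or fields[0] != "#kmer":
            raise FormatError(f"{path}:1: header must start with '#kmer'")
        sample_ids = fields[1:]
        kmers: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"got {len(parts)}"
                )
            for cell in parts[1:]:
                if cell not in ("0", "1"):
                    raise FormatError(
                        f"{path}:{lineno}: cell value {cell!r} is not 0/1"
                    )
            kmers.append(parts[0])
            rows.append([int(c) for c in parts[1:]])
    cells = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=np.uint8)
    )
    metadata: list[SampleMetadata] = []
    meta_file = _meta_path(path)
    if meta_file.exists():
        with open(meta_file) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["sample_id", "label", "group"]:
                raise FormatError(f"{meta_file}:1: bad metadata header")
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise FormatError(f"{meta_file}:{lineno}: expected 3 columns")
                metadata.append(SampleMetadata(*parts))
        if [m.sample_id for m in metadata] != sample_ids:
            raise FormatError(f"{meta_file}: sample ids disagree with {path}")
    k = kmer_core.DEFAULT_K
    partition_id: int | str = "all"
    provenance: dict = {}
    json_file = _json_path(path)
    if json_file.exists():
        with open(json_file) as fh:
            sidecar = json.load(fh)
        k = sidecar.get("k", k)
        partition_id = sidecar.get("partition_id", partition_id)
        provenance = sidecar.get("provenance", provenance)
    elif kmers:
        k = len(kmers[0])
    matrix = KmerMatrix(
        kmers=kmers,
        sample_ids=sample_ids,
        cells=cells,
        k=k,
        partition_id=partition_id,
        provenance=provenance,
    )
    return matrix, metadata
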