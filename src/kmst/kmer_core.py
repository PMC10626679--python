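"""Canonical k-mer extraction, abundance filtering and partition assignment.

A sample (a collection of sequencing reads) is reduced to the set of
canonical k-mers it contains.  Canonical means the lexicographic minimum of
a k-mer and its reverse complement, so presence is strand-insensitive.
K-mers observed fewer than ``min_abundance`` times within a sample are
treated as likely sequencing errors and dropped (default 2: singletons are
removed).  K-mers can further be assigned to one of ``num_partitions``
disjoint buckets by a salted hash, which lets downstream matrices work on a
reproducible random subset of the k-mer space.
"""

from __future__ import annotations

import gzip
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    EmptyInputError,
    InvalidBaseError,
    LengthError,
    ParameterError,
)

DEFAULT_K = 31
DEFAULT_MIN_ABUNDANCE = 2
DEFAULT_NUM_PARTITIONS = 700

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; the A<C<G<T code order makes numeric comparison of
# packed k-mers agree with lexicographic comparison of their strings
_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str, k: int | None = None) -> str:
    """Return the canonical form of ``kmer``: min(kmer, revcomp(kmer)).

    Parameters
    ----------
    kmer:
        A DNA string over {A, C, G, T}.
    k:
        If given, the required length; a mismatch raises ``LengthError``.
    """
    if k is not None and len(kmer) != k:
        raise LengthError(f"expected a {k}-mer, got length {len(kmer)}")
    if any(c not in "ACGT" for c in kmer):
        raise InvalidBaseError(f"non-ACGT character in k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class SampleKmerSet:
    """Canonical k-mers present in one sample after abundance filtering.

    ``counts`` holds the raw within-sample abundance of every observed
    canonical k-mer (pre-filter); ``kmers`` holds only those whose count is
    at least ``min_abundance``.
    """

    sample_id: str
    kmers: frozenset[str]
    counts: Mapping[str, int] = field(repr=False)
    k: int = DEFAULT_K
    min_abundance: int = DEFAULT_MIN_ABUNDANCE

    def __post_init__(self) -> None:
        for km in self.kmers:
            if len(km) != self.k:
                raise LengthError(f"k-mer {km!r} does not have length {self.k}")


def _window_codes(reads: Sequence[str], k: int) -> np.ndarray:
    """Pack every valid k-window of ``reads`` into a canonical uint64 code.

    Reads are joined with a sentinel so no window spans two reads; windows
    containing any non-ACGT character are dropped.
    """
    joined = "\x00".join(r.upper() for r in reads)
    arr = np.frombuffer(joined.encode("latin-1"), dtype=np.uint8)
    n = arr.size
    w = n - k + 1
    if w <= 0:
        return np.empty(0, dtype=np.uint64)
    base = _CODE[arr]
    invalid = (base < 0).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    window_ok = (csum[k:] - csum[:-k]) == 0
    b = np.where(base >= 0, base, 0).astype(np.uint64)
    pow4 = (np.uint64(4) ** np.arange(k, dtype=np.uint64))[::-1].copy()
    fwd = np.zeros(w, dtype=np.uint64)
    rev = np.zeros(w, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        seg = b[j : j + w]
        fwd += seg * pow4[j]
        rev += (three - seg) * pow4[k - 1 - j]
    return np.minimum(fwd, rev)[window_ok]


def _decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """Inverse of the 2-bit packing: uint64 codes back to ACGT strings."""
    codes = np.asarray(codes, dtype=np.uint64)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.empty((codes.size, k), dtype=np.uint8)
    three = np.uint64(3)
    for j in range(k):
        digit = (codes >> np.uint64(2 * (k - 1 - j))) & three
        out[:, j] = lut[digit.astype(np.intp)]
    flat = out.tobytes()
    return [flat[i * k : (i + 1) * k].decode("ascii") for i in range(codes.size)]


def extract_present_kmers(
    reads: Iterable[str],
    k: int = DEFAULT_K,
    min_abundance: int = DEFAULT_MIN_ABUNDANCE,
    sample_id: str = "sample",
) -> SampleKmerSet:
    """Extract the canonical k-mers present in a sample.

    A k-mer is *present* when its total count across all reads (both strands
    folded together by canonicalization) is at least ``min_abundance``.
    Windows spanning ambiguous bases (N, IUPAC codes, ...) are skipped and
    reads shorter than ``k`` contribute nothing.

    Raises
    ------
    EmptyInputError
        If the read collection is empty.
    ParameterError
        If ``k`` or ``min_abundance`` is not positive.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if min_abundance < 1:
        raise ParameterError(f"min_abundance must be >= 1, got {min_abundance}")
    reads = list(reads)
    if not reads:
        raise EmptyInputError("no reads supplied")
    codes = _window_codes(reads, k)
    if codes.size:
        values, raw_counts = np.unique(codes, return_counts=True)
    else:
        values = np.empty(0, dtype=np.uint64)
        raw_counts = np.empty(0, dtype=np.int64)
    strings = _decode_codes(values, k)
    counts = dict(zip(strings, (int(c) for c in raw_counts)))
    present = frozenset(
        s for s, c in zip(strings, raw_counts) if c >= min_abundance
    )
    return SampleKmerSet(
        sample_id=sample_id,
        kmers=present,
        counts=counts,
        k=k,
        min_abundance=min_abundance,
    )


def assign_partition(kmer: str, num_partitions: int, salt: int = 0) -> int:
    """Deterministically map a canonical k-mer to a partition id.

    Uses a salted 64-bit blake2b hash modulo ``num_partitions``, giving
    disjoint, jointly exhaustive and approximately uniform buckets.
    """
    if num_partitions < 1:
        raise ParameterError(f"num_partitions must be >= 1, got {num_partitions}")
    digest = hashlib.blake2b(
        kmer.encode("ascii"),
        digest_size=8,
        key=salt.to_bytes(8, "little", signed=True),
    ).digest()
    return int.from_bytes(digest, "little") % num_partitions


def partition_kmers(
    kmers: Iterable[str], num_partitions: int, salt: int = 0
) -> dict[int, set[str]]:
    """Split a k-mer collection into its hash partitions."""
    buckets: dict[int, set[str]] = {}
    for km in kmers:
        buckets.setdefault(assign_partition(km, num_partitions, salt), set()).add(km)
    return buckets


def _open_text(path: Path) -> io.TextIOBase:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b" or path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_sequences(path: str | Path) -> list[str]:
    """Read all sequences from a FASTA or FASTQ file, plain or gzipped.

    The format is sniffed from the first record character ('>' FASTA,
    '@' FASTQ); compression from the gzip magic bytes or a .gz suffix.
    FASTQ quality strings are ignored.
    """
    path = Path(path)
    with _open_text(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            raise EmptyInputError(f"{path} is empty")
        else:
            raise InvalidBaseError(f"{path} is neither FASTA nor FASTQ")
        return [str(rec.seq) for rec in SeqIO.parse(handle, fmt)]
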