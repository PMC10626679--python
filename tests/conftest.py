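"""Shared fixtures: tiny hand-built collections and a small simulated one."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from kmst import SampleMetadata, SimConfig, build_matrix_from_kmer_sets


def make_kmer(index: int, k: int = 5) -> str:
    """index -> a distinct k-mer (base-4 encoding over ACGT)."""
    bases = "ACGT"
    digits = []
    for _ in range(k):
        digits.append(bases[index % 4])
        index //= 4
    return "".join(reversed(digits))


def distinct_kmer_blocks(n_blocks: int, block_size: int, k: int = 5) -> list[set[str]]:
    """Pairwise-disjoint sets of canonical-safe k-mers.

    Uses only A/C so every generated k-mer is its own canonical form.
    """
    if n_blocks * block_size > 2**k:
        raise ValueError("not enough distinct A/C k-mers at this k")
    counter = itertools.count()
    blocks = []
    for _ in range(n_blocks):
        block = set()
        while len(block) < block_size:
            i = next(counter)
            km = "".join("AC"[(i >> b) & 1] for b in range(k))
            block.add(km)
        blocks.append(block)
    return blocks


@pytest.fixture
def disjoint_pool_collection():
    """8 samples, 2 per class, per-class k-mer pools disjoint across classes
    and fully shared within class — leave-one-out must be perfect."""
    classes = ("aOral", "mOral", "skin", "sediment/soil")
    blocks = distinct_kmer_blocks(4, 12, k=7)
    samples = []
    for c, (label, pool) in enumerate(zip(classes, blocks)):
        for r in range(2):
            meta = SampleMetadata(f"{label}-{r}", label, f"{label}-g{r}")
            samples.append((meta, set(pool)))
    matrix, metadata = build_matrix_from_kmer_sets(samples, min_recurrence=2)
    return matrix, metadata


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_simulated_collection():
    """One small simulated collection reused by read-level tests."""
    import kmst

    config = SimConfig(
        seed=11,
        pool_length=6000,
        samples_per_env=2,
        groups_per_env=2,
        coverage=3.0,
    )
    return kmst.generate_collection(config, mixtures=[{"aOral": 0.7, "skin": 0.3}])
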