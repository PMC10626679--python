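"""Synthetic labelled metagenome collections with known ground truth.

The generator emulates the statistical structure the estimator relies on:
each environment owns a "pan-genome" pool of sequence, pools of related
environments share a fraction of their content (e.g. modern oral and skin,
ancient and modern oral), every sample draws a contiguous subset of its
environment's pool, and mixture sinks combine reads from several pools at
known weights.  Reads carry i.i.d. substitution errors; there are no
indels and no ancient-DNA damage patterns, since presence/absence counting
is insensitive to where on the fragment an error falls.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .matrix_build import DEFAULT_CLASS_ORDER, SampleMetadata

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_overlap(env_names: Sequence[str]) -> dict[tuple[str, str], float]:
    """10% sharing between adjacent environments, none otherwise."""
    return {
        (env_names[i], env_names[i + 1]): 0.10
        for i in range(len(env_names) - 1)
    }


@dataclass
class SimConfig:
    """Parameters of one synthetic collection.

    seed is mandatory; all randomness flows from it.
    """

    seed: int
    n_environments: int = 4
    env_names: tuple[str, ...] | None = None
    pool_length: int = 100_000
    overlap: Mapping[tuple[str, str], float] | None = None
    samples_per_env: int = 5
    groups_per_env: int = 2
    read_length: int = 100
    coverage: float = 5.0
    error_rate: float = 0.005
    sample_subset_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.env_names is None:
            base = DEFAULT_CLASS_ORDER
            if self.n_environments <= len(base):
                self.env_names = base[: self.n_environments]
            else:
                extra = tuple(
                    f"env{i}" for i in range(len(base), self.n_environments)
                )
                self.env_names = base + extra
        self.env_names = tuple(self.env_names)
        if len(self.env_names) != self.n_environments:
            raise ConfigError("env_names length disagrees with n_environments")
        if self.overlap is None:
            self.overlap = _default_overlap(self.env_names)
        for frac in (
            self.error_rate,
            self.sample_subset_fraction,
            *self.overlap.values(),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fraction {frac} outside [0, 1]")
        if self.pool_length < self.read_length:
            raise ConfigError("pool_length must be >= read_length")
        shared_in: dict[str, float] = {}
        for (_, b), frac in self.overlap.items():
            shared_in[b] = shared_in.get(b, 0.0) + frac
        for env, total in shared_in.items():
            if total > 1.0:
                raise ConfigError(
                    f"overlap fractions copied into {env!r} sum to {total} > 1"
                )


@dataclass
class TruthRecord:
    """Ground-truth composition of one synthetic sample."""

    sample_id: str
    weights: dict[str, float]
    group: str

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"weights of {self.sample_id} sum to {total}, not 1")

    @property
    def is_pure(self) -> bool:
        return any(abs(w - 1.0) <= 1e-9 for w in self.weights.values())

    @property
    def top_env(self) -> str:
        return max(self.weights, key=self.weights.get)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def make_environment_pools(config: SimConfig) -> dict[str, str]:
    """Generate one pan-genome pool per environment.

    Pools are i.i.d. uniform ACGT; for every configured overlapping pair
    (a, b) a contiguous block of the given fraction of a's pool is copied
    into b, so the two environments share roughly block_length - k + 1
    distinct k-mers.
    """
    rng = np.random.default_rng(config.seed)
    pools = {
        env: rng.integers(0, 4, size=config.pool_length).astype(np.uint8)
        for env in config.env_names
    }
    cursor = {env: 0 for env in config.env_names}
    for (a, b) in sorted(config.overlap):
        frac = config.overlap[(a, b)]
        if frac <= 0:
            continue
        if a not in pools or b not in pools:
            raise ConfigError(f"overlap pair ({a}, {b}) names an unknown pool")
        block = int(round(frac * config.pool_length))
        src = int(rng.integers(0, config.pool_length - block + 1))
        dst = cursor[b]
        pools[b][dst : dst + block] = pools[a][src : src + block]
        cursor[b] += block
    return {env: _decode(arr) for env, arr in pools.items()}


def simulate_sample(
    pools: Mapping[str, str],
    weights: Mapping[str, float],
    config: SimConfig,
    sample_id: str,
    group: str,
    seed: int,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Draw one sample's reads from a weighted mixture of pools.

    Each contributing pool is first restricted to a random contiguous
    subset of ``sample_subset_fraction`` of its length (so two samples of
    the same environment overlap but do not coincide); the total read count
    is round(coverage x effective_length / read_length) where
    effective_length sums the subset lengths of contributing pools, and
    reads are split across pools by largest-remainder rounding of the
    weights.  Substitution errors are applied per base at ``error_rate``.
    Returns (read_id, sequence) pairs and the truth record.
    """
    active = [(env, w) for env, w in weights.items() if w > 0]
    if not active:
        raise ConfigError("mixture weights are all zero")
    for env, _ in active:
        if env not in pools:
            raise ConfigError(f"weight given for unknown environment {env!r}")
    rng = np.random.default_rng(seed)
    subsets: dict[str, np.ndarray] = {}
    for env, _ in active:
        pool = np.frombuffer(pools[env].encode("ascii"), dtype=np.uint8)
        codes = np.searchsorted(_BASES, pool)  # ACGT are sorted already
        sub_len = int(round(config.sample_subset_fraction * codes.size))
        sub_len = max(sub_len, config.read_length)
        start = int(rng.integers(0, codes.size - sub_len + 1))
        subsets[env] = codes[start : start + sub_len]
    effective_length = sum(s.size for s in subsets.values())
    n_reads = int(round(config.coverage * effective_length / config.read_length))
    total_w = sum(w for _, w in active)
    shares = [w / total_w * n_reads for _, w in active]
    counts = [int(np.floor(s)) for s in shares]
    remainder = n_reads - sum(counts)
    by_frac = sorted(
        range(len(active)), key=lambda i: (-(shares[i] - counts[i]), i)
    )
    for i in by_frac[:remainder]:
        counts[i] += 1
    reads: list[tuple[str, str]] = []
    for (env, _), n_env in zip(active, counts):
        if n_env == 0:
            continue
        sub = subsets[env]
        starts = rng.integers(0, sub.size - config.read_length + 1, size=n_env)
        idx = starts[:, None] + np.arange(config.read_length)[None, :]
        mat = sub[idx]
        if config.error_rate > 0:
            err = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat.shape)
            mat = np.where(err, (mat + shift) % 4, mat)
        for i in range(n_env):
            reads.append((f"{sample_id}|{env}|{i}", _decode(mat[i])))
    truth = TruthRecord(
        sample_id=sample_id,
        weights={env: w / total_w for env, w in weights.items() if w > 0},
        group=group,
    )
    return reads, truth


def to_fastq(reads: Sequence[tuple[str, str]], quality_char: str = "I") -> str:
    """Render (read_id, sequence) pairs as FASTQ text with constant quality."""
    chunks = []
    for rid, seq in reads:
        chunks.append(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
    return "".join(chunks)


@dataclass
class Collection:
    """An in-memory synthetic collection: labelled sources plus sinks."""

    config: SimConfig
    pools: dict[str, str]
    sources: list[tuple[SampleMetadata, list[tuple[str, str]]]]
    sinks: list[tuple[str, list[tuple[str, str]]]]
    truth: list[TruthRecord] = field(default_factory=list)

    def source_reads(self) -> list[tuple[SampleMetadata, list[str]]]:
        """Sources with bare sequences, ready for matrix building."""
        return [
            (meta, [seq for _, seq in reads]) for meta, reads in self.sources
        ]


def _sample_seed(base_seed: int, index: int) -> int:
    # distinct, reproducible per-sample streams below 2^31
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def generate_collection(
    config: SimConfig,
    mixtures: Sequence[Mapping[str, float]] = (),
) -> Collection:
    """Generate pure-label source samples plus optional mixture sinks.

    Each environment contributes ``samples_per_env`` pure samples, assigned
    round-robin to ``groups_per_env`` pseudo-BioProject groups.  Mixture
    sinks are generated last, one per weight mapping.
    """
    pools = make_environment_pools(config)
    sources = []
    truth: list[TruthRecord] = []
    counter = 0
    for env in config.env_names:
        env_tag = env.replace("/", "_")
        for i in range(config.samples_per_env):
            sample_id = f"{env_tag}_s{i}"
            group = f"{env_tag}_g{i % config.groups_per_env}"
            reads, rec = simulate_sample(
                pools,
                {env: 1.0},
                config,
                sample_id,
                group,
                seed=_sample_seed(config.seed, counter),
            )
            sources.append((SampleMetadata(sample_id, env, group), reads))
            truth.append(rec)
            counter += 1
    sinks = []
    for i, weights in enumerate(mixtures):
        sample_id = f"sink{i}"
        reads, rec = simulate_sample(
            pools,
            dict(weights),
            config,
            sample_id,
            group="sink",
            seed=_sample_seed(config.seed, counter),
        )
        sinks.append((sample_id, reads))
        truth.append(rec)
        counter += 1
    return Collection(
        config=config, pools=pools, sources=sources, sinks=sinks, truth=truth
    )


def write_collection(
    collection: Collection, out_dir: str | Path, force: bool = False
) -> Path:
    """Write FASTQ files, samples.tsv and truth.tsv for a collection.

    samples.tsv (sample_id, label, group, reads_path) covers the labelled
    sources; truth.tsv lists the ground-truth weights of every sample
    including mixture sinks.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta, reads in collection.sources:
        fq = out_dir / f"{meta.sample_id}.fastq"
        fq.write_text(to_fastq(reads))
        rows.append((meta.sample_id, meta.label, meta.group, fq.name))
    for sample_id, reads in collection.sinks:
        (out_dir / f"{sample_id}.fastq").write_text(to_fastq(reads))
    with open(out_dir / "samples.tsv", "w", newline="\n") as fh:
        fh.write("sample_id\tlabel\tgroup\treads_path\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    env_order = list(collection.config.env_names)
    with open(out_dir / "truth.tsv", "w", newline="\n") as fh:
        fh.write("sample_id\tgroup\t" + "\t".join(env_order) + "\n")
        for rec in collection.truth:
            ws = "\t".join(f"{rec.weights.get(env, 0.0):.6g}" for env in env_order)
            fh.write(f"{rec.sample_id}\t{rec.group}\t{ws}\n")
    return out_dir
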