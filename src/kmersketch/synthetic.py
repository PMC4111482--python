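"""Deterministic synthetic data: random genomes, simulated reads, random k-mers.

These generators reproduce the statistical structure of the test inputs
used to characterise counting error: i.i.d. uniform genomes, fixed-length
reads sampled uniformly at a given fold-coverage with substitution errors,
and fully random k-mer "reads" whose abundance distribution is maximally
left-skewed (essentially all counts 1 for n << 4^k).  Everything is
bit-reproducible under a fixed seed.

The error model is substitution-only: each base is replaced, with the
stated probability, by one of the three other bases chosen uniformly.
Reads are sampled from a single strand of a linear genome; counting is
strand-canonical downstream, so this loses no generality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .seqio import ReadRecord

__all__ = ["SimParams", "random_genome", "simulate_reads", "random_kmer_reads"]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SimParams:
    """Read-simulation parameters.

    ``coverage`` is fold-coverage of the genome; ``error_rate`` the
    per-base substitution probability.
    """

    genome_length: int
    read_length: int
    coverage: float
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")

    @property
    def n_reads(self) -> int:
        return math.ceil(self.coverage * self.genome_length / self.read_length)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def random_genome(length: int, seed: int) -> str:
    """An i.i.d. uniform A/C/G/T string of the given length."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return _codes_to_str(rng.integers(0, 4, size=length, dtype=np.uint8))


def simulate_reads(genome: str, params: SimParams) -> Iterator[ReadRecord]:
    """Sample fixed-length reads with substitution errors from a genome.

    Emits ``ceil(coverage * len(genome) / read_length)`` reads with uniform
    start positions.  With ``error_rate == 0`` every read is an exact
    substring of the genome.
    """
    genome_len = len(genome)
    if params.read_length > genome_len:
        raise ValueError(
            f"read_length {params.read_length} exceeds genome length {genome_len}"
        )
    rng = np.random.default_rng(params.seed)
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lookup = np.zeros(256, dtype=np.uint8)
    for base, code in _CODE_OF.items():
        lookup[ord(base)] = code
    codes = lookup[codes]

    n = params.n_reads
    length = params.read_length
    starts = rng.integers(0, genome_len - length + 1, size=n)
    batch = max(1, min(n, 1 << 16))
    for lo in range(0, n, batch):
        chunk_starts = starts[lo : lo + batch]
        rows = codes[chunk_starts[:, None] + np.arange(length)]
        if params.error_rate > 0:
            err = rng.random(rows.shape) < params.error_rate
            shifts = rng.integers(1, 4, size=rows.shape, dtype=np.uint8)
            rows = np.where(err, (rows + shifts) % 4, rows)
        block = _BASE_BYTES[rows].tobytes().decode("ascii")
        for i in range(rows.shape[0]):
            idx = lo + i
            yield ReadRecord(
                id=f"read{idx} pos={int(starts[idx])}",
                sequence=block[i * length : (i + 1) * length],
            )


def random_kmer_reads(n_kmers: int, k: int, seed: int) -> Iterator[ReadRecord]:
    """Reads of length exactly k with i.i.d. uniform bases.

    The resulting k-mer multiset is (nearly) uniform over k-mer space, so
    for n << 4^k almost every k-mer has abundance 1.
    """
    if n_kmers < 1:
        raise ValueError(f"n_kmers must be >= 1, got {n_kmers}")
    rng = np.random.default_rng(seed)
    batch = max(1, min(n_kmers, 1 << 16))
    emitted = 0
    while emitted < n_kmers:
        size = min(batch, n_kmers - emitted)
        rows = rng.integers(0, 4, size=(size, k), dtype=np.uint8)
        block = _BASE_BYTES[rows].tobytes().decode("ascii")
        for i in range(size):
            yield ReadRecord(
                id=f"kmer{emitted + i}",
                sequence=block[i * k : (i + 1) * k],
            )
        emitted += size
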