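"""Count-Min Sketch with saturating 8-bit counters.

Z tables, each a prime number of counters long, are addressed by a single
64-bit k-mer hash reduced modulo each table's size; varying the modulus
varies the hash function.  Increments touch every table; retrieval takes
the minimum across tables, so the error is one-sided: counts are never
under-reported (below the 255 counter cap).  Collisions are explicitly not
handled.
"""

from __future__ import annotations

import gzip
import struct
from typing import BinaryIO, Sequence

import numpy as np

from .kmer_codec import KmerConfig
from .sizing import is_prime

__all__ = ["CountMinSketch", "SketchParameterError", "SketchFormatError", "COUNTER_MAX"]

COUNTER_MAX = 255

_MAGIC = b"KCMS"
_VERSION = 1
_HEADER = struct.Struct("<4sBBBI")  # magic, version, k, canonical, Z
_SIZE = struct.Struct("<Q")


class SketchParameterError(ValueError):
    """Raised for invalid sketch geometry."""


class SketchFormatError(ValueError):
    """Raised when a sketch file is malformed."""


class CountMinSketch:
    """Fixed-memory online counter for k-mer hashes.

    Parameters
    ----------
    table_sizes:
        Pairwise-distinct primes, one per table.  Distinctness is what
        de-correlates the tables under the shared base hash, and primality
        keeps the moduli free of shared factors.
    config:
        K-mer length and canonicalization policy the hashes were produced
        under (stored for persistence and for sanity checks by callers).
    """

    def __init__(self, table_sizes: Sequence[int], config: KmerConfig):
        sizes = [int(s) for s in table_sizes]
        if not sizes:
            raise SketchParameterError("at least one table is required")
        if len(set(sizes)) != len(sizes):
            raise SketchParameterError(f"table sizes must be distinct: {sizes}")
        for s in sizes:
            if not is_prime(s):
                raise SketchParameterError(f"table size {s} is not prime")
        self.config = config
        self.table_sizes = tuple(sizes)
        self.tables = [np.zeros(s, dtype=np.uint8) for s in sizes]
        self._sizes_u64 = np.asarray(sizes, dtype=np.uint64)
        self.n_kmers_consumed = 0

    # -- core operations ---------------------------------------------------

    def increment(self, kmer_hash: int) -> int:
        """Increment a single k-mer and return its post-increment estimate.

        Counters saturate at 255; there is no wraparound.
        """
        if kmer_hash < 0:
            raise ValueError("kmer hash must be non-negative")
        est = COUNTER_MAX
        for table, size in zip(self.tables, self.table_sizes):
            i = kmer_hash % size
            if table[i] < COUNTER_MAX:
                table[i] += 1
            est = min(est, int(table[i]))
        self.n_kmers_consumed += 1
        return est

    def get_count(self, kmer_hash: int) -> int:
        """Minimum count across tables; never below the true count (<= 255)."""
        if kmer_hash < 0:
            raise ValueError("kmer hash must be non-negative")
        return min(
            int(table[kmer_hash % size])
            for table, size in zip(self.tables, self.table_sizes)
        )

    def update(self, hashes: np.ndarray) -> None:
        """Bulk-increment an array of k-mer hashes.

        Equivalent to calling :meth:`increment` for each element (saturating
        addition commutes, so per-table totals can be applied with a single
        clipped add).
        """
        hashes = np.ascontiguousarray(hashes, dtype=np.uint64)
        if hashes.size == 0:
            return
        for table, size in zip(self.tables, self._sizes_u64):
            idx = (hashes % size).astype(np.int64)
            delta = np.bincount(idx, minlength=int(size))
            np.minimum(table + delta, COUNTER_MAX, out=delta)
            table[:] = delta.astype(np.uint8)
        self.n_kmers_consumed += int(hashes.size)

    def get_counts(self, hashes: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`get_count`; returns a uint8 array."""
        hashes = np.ascontiguousarray(hashes, dtype=np.uint64)
        out = np.full(hashes.shape, COUNTER_MAX, dtype=np.uint8)
        for table, size in zip(self.tables, self._sizes_u64):
            np.minimum(out, table[(hashes % size).astype(np.int64)], out=out)
        return out

    def estimate_fp_rate(self) -> float:
        """Empirical false positive rate: product of table occupancies."""
        rate = 1.0
        for table in self.tables:
            rate *= np.count_nonzero(table) / table.size
        return rate

    # -- persistence -------------------------------------------------------

    def save(self, path: str, compress: bool | None = None) -> None:
        """Write the sketch to ``path``.

        ``compress`` defaults to whether the path ends in ``.gz``.  Layout
        (little-endian): magic ``KCMS``, version byte, k, canonical flag,
        table count as uint32, then per table a uint64 size followed by the
        raw counter bytes.
        """
        if compress is None:
            compress = str(path).endswith(".gz")
        opener = gzip.open if compress else open
        with opener(path, "wb") as fh:
            fh.write(
                _HEADER.pack(
                    _MAGIC,
                    _VERSION,
                    self.config.k,
                    int(self.config.canonical),
                    len(self.tables),
                )
            )
            fh.write(_SIZE.pack(self.n_kmers_consumed))
            for table in self.tables:
                fh.write(_SIZE.pack(table.size))
                fh.write(table.tobytes())

    @classmethod
    def load(cls, path: str) -> "CountMinSketch":
        """Read a sketch written by :meth:`save` (gzip detected by magic)."""
        with open(path, "rb") as raw:
            head = raw.read(2)
            raw.seek(0)
            fh: BinaryIO
            if head == b"\x1f\x8b":
                fh = gzip.open(raw, "rb")  # type: ignore[assignment]
            else:
                fh = raw
            return cls._read(fh, path)

    @classmethod
    def _read(cls, fh: BinaryIO, path: str) -> "CountMinSketch":
        header = fh.read(_HEADER.size)
        if len(header) < _HEADER.size:
            raise SketchFormatError(f"{path}: truncated header")
        magic, version, k, canonical, n_tables = _HEADER.unpack(header)
        if magic != _MAGIC:
            raise SketchFormatError(f"{path}: bad magic bytes {magic!r}")
        if version != _VERSION:
            raise SketchFormatError(f"{path}: unsupported format version {version}")
        consumed_raw = fh.read(_SIZE.size)
        if len(consumed_raw) < _SIZE.size:
            raise SketchFormatError(f"{path}: truncated header")
        (consumed,) = _SIZE.unpack(consumed_raw)
        sizes: list[int] = []
        tables: list[np.ndarray] = []
        for t in range(n_tables):
            size_raw = fh.read(_SIZE.size)
            if len(size_raw) < _SIZE.size:
                raise SketchFormatError(f"{path}: truncated at table {t}")
            (size,) = _SIZE.unpack(size_raw)
            data = fh.read(size)
            if len(data) < size:
                raise SketchFormatError(f"{path}: truncated counters in table {t}")
            sizes.append(size)
            tables.append(np.frombuffer(data, dtype=np.uint8).copy())
        sketch = cls(sizes, KmerConfig(k=k, canonical=bool(canonical)))
        for dst, src in zip(sketch.tables, tables):
            dst[:] = src
        sketch.n_kmers_consumed = consumed
        return sketch

    # -- conveniences ------------------------------------------------------

    @property
    def memory(self) -> int:
        """Total number of counters (one byte each)."""
        return sum(self.table_sizes)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CountMinSketch(k={self.config.k}, Z={len(self.tables)}, "
            f"memory={self.memory}, consumed={self.n_kmers_consumed})"
        )
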