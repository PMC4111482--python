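"""Exact 2-bit encoding of DNA k-mers into 64-bit integers.

A k-mer of length k <= 32 is encoded base-4 positionally (A=0, C=1, G=2,
T=3, most-significant base first), which is a bijection between the 4^k
k-mers and the integers [0, 4^k).  Canonical (strand-neutral) hashing takes
the lower of the encodings of a k-mer and its reverse complement.

Besides the scalar operations, this module provides vectorised hashing of
whole reads (and batches of reads) used by the counting applications;
windows containing any non-ACGT character are skipped, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "KmerConfig",
    "InvalidKmerError",
    "encode_kmer",
    "decode_kmer",
    "reverse_complement",
    "canonical_hash",
    "kmer_hashes",
    "batch_kmer_hashes",
    "iter_kmers",
]

MAX_K = 32

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

# byte -> 2-bit code; 0xFF marks anything that is not A/C/G/T
_CODES = np.full(256, 0xFF, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i

# windows are hashed in chunks to bound the (n_windows x k) temporaries
_CHUNK = 1 << 19


class InvalidKmerError(ValueError):
    """Raised for k-mers with invalid length or non-ACGT characters."""


@dataclass(frozen=True)
class KmerConfig:
    """K-mer length and canonicalization policy.

    Parameters
    ----------
    k:
        K-mer length in bases; must satisfy ``1 <= k <= 32`` (the encoding
        packs 2 bits per base into a 64-bit integer).
    canonical:
        When true (the default), hashing is strand-neutral: a k-mer and its
        reverse complement map to the same value.
    """

    k: int
    canonical: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)):
            raise TypeError(f"k must be an integer, got {self.k!r}")
        if not 1 <= self.k <= MAX_K:
            raise InvalidKmerError(f"k must be in [1, {MAX_K}], got {self.k}")

    @property
    def n_kmers(self) -> int:
        """Size of k-mer space, 4**k."""
        return 4 ** self.k


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _codes_or_raise(seq: str, k: int) -> np.ndarray:
    if len(seq) != k:
        raise InvalidKmerError(f"expected a {k}-mer, got length {len(seq)}")
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODES[raw]
    if (codes == 0xFF).any():
        bad = seq[int(np.argmax(codes == 0xFF))]
        raise InvalidKmerError(f"non-ACGT character {bad!r} in k-mer {seq!r}")
    return codes


def encode_kmer(seq: str, config: KmerConfig) -> int:
    """Encode a k-mer into its base-4 integer value (MSB-first)."""
    codes = _codes_or_raise(seq, config.k)
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def decode_kmer(value: int, config: KmerConfig) -> str:
    """Invert :func:`encode_kmer`."""
    if not 0 <= value < config.n_kmers:
        raise InvalidKmerError(
            f"encoded value {value} out of range for k={config.k}"
        )
    out = []
    for shift in range(2 * (config.k - 1), -1, -2):
        out.append(_BASES[(value >> shift) & 3])
    return "".join(out)


def canonical_hash(seq: str, config: KmerConfig) -> int:
    """Hash a k-mer, taking the strand-lower encoding when canonical."""
    fwd = encode_kmer(seq, config)
    if not config.canonical:
        return fwd
    # reverse complement in code space: complement of code c is 3 - c
    codes = _CODES[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    rev = 0
    for c in codes[::-1]:
        rev = (rev << 2) | (3 - int(c))
    return min(fwd, rev)


def kmer_hashes(seq: str, config: KmerConfig) -> tuple[np.ndarray, np.ndarray]:
    """Hash every valid k-length window of ``seq``.

    Returns ``(positions, hashes)`` where ``positions`` are the 0-based
    start coordinates of windows consisting solely of A/C/G/T (case
    insensitive), in left-to-right order, and ``hashes`` the corresponding
    (canonical) encodings as uint64.  Degenerate inputs yield empty arrays.
    """
    k = config.k
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODES[raw]
    n = codes.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return np.empty(0, dtype=np.int64), empty

    # a window is valid iff it contains no invalid byte: O(n) via prefix sums
    bad_prefix = np.zeros(codes.size + 1, dtype=np.int64)
    np.cumsum(codes == 0xFF, out=bad_prefix[1:])
    positions = np.flatnonzero(bad_prefix[k:] == bad_prefix[:-k]).astype(np.int64)
    if positions.size == 0:
        return positions, np.empty(0, dtype=np.uint64)

    clean = np.where(codes == 0xFF, 0, codes)  # uint8; gathered per chunk
    offsets = np.arange(k, dtype=np.int64)
    fwd_w = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    rev_w = fwd_w[::-1]
    three = np.uint64(3)
    hashes = np.empty(positions.size, dtype=np.uint64)
    for lo in range(0, positions.size, _CHUNK):
        p = positions[lo : lo + _CHUNK]
        w = clean[p[:, None] + offsets].astype(np.uint64)
        fwd = (w * fwd_w).sum(axis=1, dtype=np.uint64)
        if config.canonical:
            rev = ((three - w) * rev_w).sum(axis=1, dtype=np.uint64)
            np.minimum(fwd, rev, out=fwd)
        hashes[lo : lo + _CHUNK] = fwd
    return positions, hashes


def batch_kmer_hashes(
    seqs: Iterable[str], config: KmerConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hash the k-mers of many reads in one vectorised pass.

    Joins the sequences with an ``N`` separator (so no window spans two
    reads) and returns ``(read_indices, positions, hashes)`` where
    ``positions`` are local to each read.
    """
    seqs = list(seqs)
    if not seqs:
        e64 = np.empty(0, dtype=np.int64)
        return e64, e64.copy(), np.empty(0, dtype=np.uint64)
    joined = "N".join(seqs)
    offsets = np.zeros(len(seqs), dtype=np.int64)
    if len(seqs) > 1:
        lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64)
        offsets[1:] = np.cumsum(lengths[:-1] + 1)
    gpos, hashes = kmer_hashes(joined, config)
    read_idx = np.searchsorted(offsets, gpos, side="right") - 1
    local = gpos - offsets[read_idx]
    return read_idx, local, hashes


def iter_kmers(seq: str, config: KmerConfig) -> Iterator[tuple[int, int]]:
    """Yield ``(start_position, kmer_hash)`` for each valid window of a read."""
    positions, hashes = kmer_hashes(seq, config)
    for p, h in zip(positions.tolist(), hashes.tolist()):
        yield p, h
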