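"""Applications built on the counting sketch.

Four analyses: k-mer abundance histograms, per-position unique-k-mer error
profiles, (iterative) truncation of reads at low-abundance k-mers, and
streaming digital normalization.  Histograms and profiles are two-pass
(count, then re-stream); normalization is single-pass and never loads
discarded reads into the sketch, so its false positive rate does not grow
with discarded data.

Report-level distinct/unique k-mer tallies use an exact counter (the
sketch stores counts, not k-mers); this is separate from the sketch path
and intended for desk-scale evaluation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .kmer_codec import KmerConfig, batch_kmer_hashes, kmer_hashes
from .seqio import ReadRecord, stream_reads, write_reads
from .sketch import COUNTER_MAX, CountMinSketch
from .sizing import primes_at_or_below

__all__ = [
    "AbundanceHistogram",
    "PositionProfile",
    "TrimIteration",
    "TrimReport",
    "NormalizationReport",
    "load_reads_into_sketch",
    "abundance_histogram",
    "unique_kmer_position_profile",
    "trim_read_at_low_abundance",
    "iterative_trim",
    "digital_normalize",
]

_BATCH = 50_000  # reads per vectorised batch


# ---------------------------------------------------------------------------
# report types


@dataclass
class AbundanceHistogram:
    """Distinct k-mers per abundance value (1..255, as reported by the sketch)."""

    counts: np.ndarray  # length 256; counts[a] = distinct k-mers at abundance a
    n_distinct: int
    n_total: int
    k: int

    def as_dict(self) -> dict[int, int]:
        return {a: int(c) for a, c in enumerate(self.counts) if c}

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            out.write("abundance\tcount\n")
            for a, c in enumerate(self.counts):
                if c:
                    out.write(f"{a}\t{int(c)}\n")


@dataclass
class PositionProfile:
    """Unique-k-mer instances by 0-based k-mer start position within reads."""

    unique_by_position: np.ndarray
    read_length: int
    k: int

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            out.write("position\tunique_kmers\n")
            for p, c in enumerate(self.unique_by_position):
                out.write(f"{p}\t{int(c)}\n")


@dataclass
class TrimIteration:
    """One round of low-abundance trimming (columns mirror the trim report TSV)."""

    iteration: int
    fp_rate: float
    bases_trimmed_fraction: float  # of the original input bases, this round
    distinct_kmers: int
    unique_kmers: int
    unique_at_3prime_fraction: float
    reads_kept: int
    output_path: str


@dataclass
class TrimReport:
    iterations: list[TrimIteration] = field(default_factory=list)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            out.write(
                "iteration\tFP rate\tbases trimmed\tdistinct k-mers\t"
                "unique k-mers\tunique k-mers at 3' end\n"
            )
            for row in self.iterations:
                out.write(
                    f"{row.iteration}\t{row.fp_rate:.4f}\t"
                    f"{row.bases_trimmed_fraction:.4f}\t{row.distinct_kmers}\t"
                    f"{row.unique_kmers}\t{row.unique_at_3prime_fraction:.4f}\n"
                )


@dataclass
class NormalizationReport:
    fp_rate: float
    reads_total: int
    reads_kept: int
    distinct_before: int
    distinct_after: int
    coverage: int

    @property
    def fraction_kept(self) -> float:
        return self.reads_kept / self.reads_total if self.reads_total else 0.0

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            out.write(
                "FP rate\tretained reads\tretained reads %\t"
                "distinct k-mers before\tdistinct k-mers after\tC\n"
            )
            out.write(
                f"{self.fp_rate:.4f}\t{self.reads_kept}\t"
                f"{100.0 * self.fraction_kept:.1f}%\t{self.distinct_before}\t"
                f"{self.distinct_after}\t{self.coverage}\n"
            )


# ---------------------------------------------------------------------------
# helpers


def _read_batches(source, batch: int = _BATCH) -> Iterator[list[ReadRecord]]:
    if isinstance(source, (str, os.PathLike)):
        source = stream_reads(str(source))
    chunk: list[ReadRecord] = []
    for rec in source:
        chunk.append(rec)
        if len(chunk) >= batch:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def load_reads_into_sketch(reads, sketch: CountMinSketch) -> tuple[int, int]:
    """Pass 1: count every k-mer of every read; returns (n_reads, n_kmers)."""
    n_reads = n_kmers = 0
    for chunk in _read_batches(reads):
        _, _, hashes = batch_kmer_hashes(
            (r.sequence for r in chunk), sketch.config
        )
        sketch.update(hashes)
        n_reads += len(chunk)
        n_kmers += hashes.size
    return n_reads, n_kmers


def _exact_spectrum(hash_arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """(distinct hashes, exact counts) over a list of hash arrays."""
    if not hash_arrays:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allh = np.concatenate(hash_arrays)
    return np.unique(allh, return_counts=True)


# ---------------------------------------------------------------------------
# abundance histogram


def abundance_histogram(
    reads, sketch: CountMinSketch, k: Optional[int] = None
) -> AbundanceHistogram:
    """Pass 2: histogram of sketch-reported abundances over distinct k-mers.

    The sketch must already hold the same reads (pass 1 via
    :func:`load_reads_into_sketch`).  Each distinct k-mer contributes once,
    at its sketch-reported abundance; collisions shift mass upward, never
    downward.
    """
    if k is not None and k != sketch.config.k:
        raise ValueError(f"k mismatch: sketch has k={sketch.config.k}, got k={k}")
    hash_arrays: list[np.ndarray] = []
    n_total = 0
    for chunk in _read_batches(reads):
        _, _, hashes = batch_kmer_hashes(
            (r.sequence for r in chunk), sketch.config
        )
        hash_arrays.append(hashes)
        n_total += hashes.size
    distinct, _ = _exact_spectrum(hash_arrays)
    counts = np.zeros(COUNTER_MAX + 1, dtype=np.int64)
    if distinct.size:
        abundances = sketch.get_counts(distinct)
        counts += np.bincount(abundances, minlength=COUNTER_MAX + 1)
    return AbundanceHistogram(
        counts=counts,
        n_distinct=int(distinct.size),
        n_total=n_total,
        k=sketch.config.k,
    )


# ---------------------------------------------------------------------------
# unique-k-mer position profile


def unique_kmer_position_profile(reads, sketch: CountMinSketch) -> PositionProfile:
    """Count k-mer instances with sketch abundance 1, by start position.

    One-sided sketch error can only depress unique calls (a truly unique
    k-mer may be miscounted upward), never inflate them.
    """
    k = sketch.config.k
    profile = np.zeros(0, dtype=np.int64)
    max_len = 0
    for chunk in _read_batches(reads):
        max_len = max(max_len, max(len(r) for r in chunk))
        n_positions = max_len - k + 1
        if n_positions > profile.size:
            profile = np.concatenate(
                [profile, np.zeros(n_positions - profile.size, dtype=np.int64)]
            )
        _, pos, hashes = batch_kmer_hashes(
            (r.sequence for r in chunk), sketch.config
        )
        if hashes.size:
            unique = sketch.get_counts(hashes) == 1
            np.add.at(profile, pos[unique], 1)
    return PositionProfile(
        unique_by_position=profile, read_length=max_len, k=k
    )


# ---------------------------------------------------------------------------
# trimming


def trim_read_at_low_abundance(
    read: ReadRecord, sketch: CountMinSketch, cutoff: int = 1
) -> Optional[ReadRecord]:
    """Truncate a read at its first k-mer with sketch count <= cutoff.

    The read keeps its first ``p + k - 1`` bases, where ``p`` is the start
    of the offending k-mer (its final base is dropped).  Returns the read
    unchanged if no k-mer is low-abundance (or if it has no valid k-mers),
    and ``None`` (rejection) when the surviving prefix would be shorter
    than k.  Because the sketch never undercounts, a k-mer whose true
    abundance exceeds ``cutoff`` is never a trim point.
    """
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    positions, hashes = kmer_hashes(read.sequence, sketch.config)
    if hashes.size == 0:
        return read
    low = np.flatnonzero(sketch.get_counts(hashes) <= cutoff)
    if low.size == 0:
        return read
    p = int(positions[low[0]])
    keep = p + sketch.config.k - 1
    if keep < sketch.config.k:
        return None
    return ReadRecord(
        id=read.id,
        sequence=read.sequence[:keep],
        quality=read.quality[:keep] if read.quality is not None else None,
    )


def _trim_batch(
    chunk: Sequence[ReadRecord], sketch: CountMinSketch, cutoff: int
) -> list[Optional[ReadRecord]]:
    """Vectorised trim_read_at_low_abundance over a batch of reads."""
    k = sketch.config.k
    read_idx, pos, hashes = batch_kmer_hashes(
        (r.sequence for r in chunk), sketch.config
    )
    out: list[Optional[ReadRecord]] = list(chunk)
    if hashes.size == 0:
        return out
    low = sketch.get_counts(hashes) <= cutoff
    low_idx = np.flatnonzero(low)
    if low_idx.size == 0:
        return out
    # first low-abundance window per read
    first = {}
    for j in low_idx[::-1].tolist():  # reversed so earlier windows overwrite
        first[int(read_idx[j])] = int(pos[j])
    for i, p in first.items():
        keep = p + k - 1
        if keep < k:
            out[i] = None
        else:
            r = chunk[i]
            out[i] = ReadRecord(
                id=r.id,
                sequence=r.sequence[:keep],
                quality=r.quality[:keep] if r.quality is not None else None,
            )
    return out


def iterative_trim(
    reads_path: str,
    per_table_size: int,
    z: int,
    config: KmerConfig,
    cutoff: int = 1,
    max_iterations: int = 6,
    output_dir: Optional[str] = None,
) -> TrimReport:
    """Repeated fixed-memory trimming at low-abundance k-mers.

    Each iteration builds a fresh sketch (same geometry — memory is fixed
    across rounds), counts the current reads, trims them, and writes the
    survivors to ``<stem>.roundN`` files.  Per-round statistics: empirical
    false positive rate after counting, bases removed this round as a
    fraction of the *original* input bases, exact distinct and unique
    (abundance-1) k-mers in the round's output, and the fraction of unique
    k-mer instances starting within the final k-1 bases of their read (the
    3' end).  Iteration stops early once a round removes no bases.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    table_sizes = primes_at_or_below(per_table_size, z)
    k = config.k

    directory = output_dir or os.path.dirname(os.path.abspath(reads_path))
    os.makedirs(directory, exist_ok=True)
    stem = os.path.basename(reads_path)
    if stem.endswith(".gz"):
        stem = stem[:-3]
    stem, ext = os.path.splitext(stem)
    ext = ext or ".fa"

    report = TrimReport()
    current = reads_path
    total_bases_original = 0

    for iteration in range(1, max_iterations + 1):
        sketch = CountMinSketch(table_sizes, config)
        bases_in = 0
        for chunk in _read_batches(current):
            _, _, hashes = batch_kmer_hashes(
                (r.sequence for r in chunk), config
            )
            sketch.update(hashes)
            bases_in += sum(len(r) for r in chunk)
        if iteration == 1:
            total_bases_original = bases_in
        if total_bases_original == 0:
            break
        fp = sketch.estimate_fp_rate()

        out_path = os.path.join(directory, f"{stem}.round{iteration}{ext}")
        bases_out = 0
        reads_kept = 0
        out_format = "fasta"
        hash_arrays: list[np.ndarray] = []
        pos_arrays: list[np.ndarray] = []
        margin_arrays: list[np.ndarray] = []  # per-instance L - 2k + 1 threshold

        def survivors() -> Iterator[ReadRecord]:
            nonlocal bases_out, reads_kept, out_format
            for chunk in _read_batches(current):
                kept = [
                    r for r in _trim_batch(chunk, sketch, cutoff) if r is not None
                ]
                if kept:
                    if kept[0].quality is not None:
                        out_format = "fastq"
                    ridx, pos, hashes = batch_kmer_hashes(
                        (r.sequence for r in kept), config
                    )
                    lengths = np.fromiter(
                        (len(r) for r in kept), dtype=np.int64, count=len(kept)
                    )
                    hash_arrays.append(hashes)
                    pos_arrays.append(pos)
                    margin_arrays.append(lengths[ridx] - 2 * k + 1)
                    bases_out += int(lengths.sum())
                    reads_kept += len(kept)
                yield from kept

        # buffer, then write with the detected format
        kept_records = list(survivors())
        write_reads(kept_records, out_path, format=out_format)

        distinct, counts = _exact_spectrum(hash_arrays)
        if distinct.size:
            allh = np.concatenate(hash_arrays)
            allpos = np.concatenate(pos_arrays)
            margins = np.concatenate(margin_arrays)
            inv = np.searchsorted(distinct, allh)
            inst_unique = counts[inv] == 1
            n_unique = int((counts == 1).sum())
            if inst_unique.any():
                at3p = allpos[inst_unique] > margins[inst_unique]
                frac_3p = float(at3p.mean())
            else:
                frac_3p = 0.0
        else:
            n_unique = 0
            frac_3p = 0.0

        bases_removed = bases_in - bases_out
        report.iterations.append(
            TrimIteration(
                iteration=iteration,
                fp_rate=fp,
                bases_trimmed_fraction=bases_removed / total_bases_original,
                distinct_kmers=int(distinct.size),
                unique_kmers=n_unique,
                unique_at_3prime_fraction=frac_3p,
                reads_kept=reads_kept,
                output_path=out_path,
            )
        )
        current = out_path
        if bases_removed == 0:
            break
    return report


# ---------------------------------------------------------------------------
# digital normalization


def digital_normalize(
    reads_path: str,
    sketch: CountMinSketch,
    coverage: int,
    output_path: str,
) -> NormalizationReport:
    """Streaming digital normalization to a median k-mer coverage C.

    A single pass over the reads: a read is kept (written, and its k-mers
    loaded into the sketch) only when the median of its k-mers' current
    sketch counts is below C; discarded reads never touch the sketch, so
    the false positive rate does not grow with discarded data.  The median
    is the element at index ``n // 2`` of the sorted counts.  Reads with no
    valid k-mers are discarded.  Distinct-k-mer tallies before/after are
    exact.
    """
    if coverage < 1:
        raise ValueError(f"coverage must be >= 1, got {coverage}")
    config = sketch.config
    reads_total = reads_kept = 0
    before_arrays: list[np.ndarray] = []
    after_arrays: list[np.ndarray] = []
    out_format = "fasta"

    def kept_reads() -> Iterator[ReadRecord]:
        nonlocal reads_total, reads_kept, out_format
        for rec in stream_reads(reads_path):
            reads_total += 1
            _, hashes = kmer_hashes(rec.sequence, config)
            if hashes.size == 0:
                continue
            before_arrays.append(hashes)
            counts = np.sort(sketch.get_counts(hashes))
            median = int(counts[counts.size // 2])
            if median < coverage:
                sketch.update(hashes)
                after_arrays.append(hashes)
                reads_kept += 1
                if rec.quality is not None:
                    out_format = "fastq"
                yield rec

    kept = list(kept_reads())
    write_reads(kept, output_path, format=out_format)
    distinct_before, _ = _exact_spectrum(before_arrays)
    distinct_after, _ = _exact_spectrum(after_arrays)
    return NormalizationReport(
        fp_rate=sketch.estimate_fp_rate(),
        reads_total=reads_total,
        reads_kept=reads_kept,
        distinct_before=int(distinct_before.size),
        distinct_after=int(distinct_after.size),
        coverage=coverage,
    )
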