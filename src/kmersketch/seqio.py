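"""Streaming FASTA/FASTQ input and output, plain or gzip-compressed.

Parsing is delegated to Biopython's low-level iterators
(``SimpleFastaParser`` / ``FastqGeneralIterator``), which stream records
without building SeqRecord objects; this module adds format
auto-detection, transparent gzip, and record-indexed error reporting.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["ReadRecord", "SequenceParseError", "stream_reads", "write_reads"]


class SequenceParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input, naming the offending record."""


@dataclass
class ReadRecord:
    """A single sequencing read.

    ``id`` is the full header line (without the leading ``>`` or ``@``);
    ``quality``, when present, is a Phred+33 string of the same length as
    ``sequence``.
    """

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str) -> IO[str]:
    fh = open(path, "rb")
    if fh.peek(2)[:2] == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(fh, "rb"))
    return io.TextIOWrapper(fh)


def _detect_format(handle: IO[str]) -> Optional[str]:
    while True:
        ch = handle.read(1)
        if ch == "":
            return None  # empty file -> empty stream
        if not ch.isspace():
            break
    handle.seek(0) if handle.seekable() else None
    if ch == ">":
        return "fasta"
    if ch == "@":
        return "fastq"
    raise SequenceParseError(
        f"cannot auto-detect format: first character {ch!r} is neither '>' nor '@'"
    )


def stream_reads(path: str, format: str = "auto") -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects from a FASTA/FASTQ file in order.

    ``format`` may be ``auto`` (detect by first non-blank character after
    optional gzip decoding), ``fasta`` or ``fastq``.  Memory use is
    constant in file size.
    """
    if format not in ("auto", "fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    handle = _open_text(path)
    try:
        if format == "auto":
            detected = _detect_format(handle)
            if detected is None:
                return
            if not handle.seekable():  # pragma: no cover - gzip is seekable
                handle.close()
                handle = _open_text(path)
            else:
                handle.seek(0)
            format = detected
        if format == "fasta":
            parser: Iterable = SimpleFastaParser(handle)
            for index, (title, seq) in enumerate(parser):
                if not seq:
                    raise SequenceParseError(
                        f"{path}: record {index} ({title!r}) has an empty sequence"
                    )
                yield ReadRecord(id=title, sequence=seq)
        else:
            records = FastqGeneralIterator(handle)
            index = -1
            while True:
                index += 1
                try:
                    title, seq, qual = next(records)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise SequenceParseError(
                        f"{path}: record {index}: {exc}"
                    ) from exc
                yield ReadRecord(id=title, sequence=seq, quality=qual)
    finally:
        handle.close()


def write_reads(
    records: Iterable[ReadRecord],
    path: str,
    format: str = "fasta",
    fill_quality: Optional[str] = None,
) -> int:
    """Write records as FASTA or FASTQ; returns the number written.

    Gzip compression is applied when the path ends in ``.gz``.  FASTA
    output silently drops qualities.  FASTQ output requires every record to
    carry a quality string unless ``fill_quality`` supplies a single
    character to fill with (e.g. ``"I"``).
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    if fill_quality is not None and len(fill_quality) != 1:
        raise ValueError("fill_quality must be a single character")
    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "wt") as out:
        for rec in records:
            if format == "fasta":
                out.write(f">{rec.id}\n{rec.sequence}\n")
            else:
                qual = rec.quality
                if qual is None:
                    if fill_quality is None:
                        raise ValueError(
                            f"record {rec.id!r} has no quality; FASTQ output needs "
                            "qualities or an explicit fill_quality"
                        )
                    qual = fill_quality * len(rec.sequence)
                out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n
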