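"""Miscount measurement against an exact-counter oracle.

Counts a k-mer hash stream both in a sketch and exactly (via sorting), and
summarises the per-distinct-k-mer miscount (sketch - exact) and percent
miscount ((sketch - exact) / exact * 100).  Used to characterise counting
error at controlled false positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_codec import KmerConfig
from .sketch import CountMinSketch
from .sizing import params_for_target_fp, primes_at_or_above

__all__ = ["MiscountSummary", "measure_miscount", "sketch_for_fp", "percent_miscount"]


def percent_miscount(true_count: int, reported_count: int) -> float:
    """Miscount relative to the true count, as a percentage.

    E.g. a reported count of 5 for a k-mer whose true count is 1 is a
    miscount of 4, i.e. 400%.
    """
    if true_count <= 0:
        raise ValueError("true count must be positive")
    return 100.0 * (reported_count - true_count) / true_count


@dataclass(frozen=True)
class MiscountSummary:
    n_distinct: int
    n_total: int
    expected_fp: float
    empirical_fp: float
    avg_miscount: float
    avg_pct_miscount: float
    max_exact_count: int


def sketch_for_fp(
    fp_target: float, n_distinct: int, config: KmerConfig
) -> CountMinSketch:
    """Sketch sized analytically so the expected fp rate is <= fp_target."""
    params = params_for_target_fp(fp_target, n_distinct)
    return CountMinSketch(primes_at_or_above(params.h, params.z), config)


def measure_miscount(
    hashes: np.ndarray, sketch: CountMinSketch, expected_fp: float = float("nan")
) -> MiscountSummary:
    """Count ``hashes`` in ``sketch`` and compare against exact counts.

    Averages are taken over distinct k-mers.  Exact counts above the
    sketch's 255 counter cap would make the comparison meaningless; the
    summary records the maximum exact count so callers can check.
    """
    hashes = np.ascontiguousarray(hashes, dtype=np.uint64)
    sketch.update(hashes)
    distinct, exact = np.unique(hashes, return_counts=True)
    reported = sketch.get_counts(distinct).astype(np.int64)
    miscount = reported - exact
    pct = 100.0 * miscount / exact
    return MiscountSummary(
        n_distinct=int(distinct.size),
        n_total=int(hashes.size),
        expected_fp=expected_fp,
        empirical_fp=sketch.estimate_fp_rate(),
        avg_miscount=float(miscount.mean()) if distinct.size else 0.0,
        avg_pct_miscount=float(pct.mean()) if distinct.size else 0.0,
        max_exact_count=int(exact.max()) if distinct.size else 0,
    )
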