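import numpy as np
import pytest

import kmersketch as ks
from kmersketch.kmer_codec import batch_kmer_hashes

K22 = ks.KmerConfig(k=22)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "a": 0, "c": 1, "g": 2, "t": 3}


def exact_counts(seqs, config):
    """Independent oracle: exact dict counting via a pure-Python rolling hash.

    Maintains the forward encoding (append 2 bits at the right) and the
    reverse-complement encoding (prepend complement bits at the left)
    incrementally; windows touching a non-ACGT base reset the roll.
    """
    k = config.k
    mask = 4**k - 1
    top_shift = 2 * (k - 1)
    counts: dict[int, int] = {}
    for seq in seqs:
        fwd = rc = run = 0
        for ch in seq:
            c = _BASE_CODE.get(ch)
            if c is None:
                fwd = rc = run = 0
                continue
            fwd = ((fwd << 2) | c) & mask
            rc = (rc >> 2) | ((3 - c) << top_shift)
            run += 1
            if run >= k:
                h = min(fwd, rc) if config.canonical else fwd
                counts[h] = counts.get(h, 0) + 1
    return counts


@pytest.fixture(scope="session")
def random_kmer_hashes_large():
    """~2.25M random 22-mer reads hashed canonically (Table-2 scale fixture)."""
    reads = ks.random_kmer_reads(2_250_006, 22, seed=1)
    _, _, hashes = batch_kmer_hashes((r.sequence for r in reads), K22)
    return hashes


@pytest.fixture(scope="session")
def error_free_read_class():
    """3x-coverage 100-bp reads from a random 2.2 Mbp genome, no errors."""
    genome = ks.random_genome(2_200_000, seed=7)
    params = ks.SimParams(
        genome_length=len(genome), read_length=100, coverage=3.0,
        error_rate=0.0, seed=8,
    )
    reads = list(ks.simulate_reads(genome, params))
    _, _, hashes = batch_kmer_hashes((r.sequence for r in reads), K22)
    return genome, reads, hashes


@pytest.fixture(scope="session")
def error_read_class():
    """3x-coverage 100-bp reads from a random 1 Mbp genome, 3% substitutions."""
    genome = ks.random_genome(1_000_000, seed=9)
    params = ks.SimParams(
        genome_length=len(genome), read_length=100, coverage=3.0,
        error_rate=0.03, seed=10,
    )
    reads = list(ks.simulate_reads(genome, params))
    _, _, hashes = batch_kmer_hashes((r.sequence for r in reads), K22)
    return genome, reads, hashes
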