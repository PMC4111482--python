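# kmersketch

Fixed-memory, online k-mer counting for DNA sequencing data using a
Count-Min Sketch, plus the k-mer spectral analyses that build on it:
abundance histograms, per-position sequencing-error profiling, iterative
low-abundance read trimming, and streaming digital normalization.

The sketch stores only counts, never k-mers: Z hash tables, each a distinct
prime number of 8-bit saturating counters, addressed by an exact 2-bit
encoding of each k-mer (k ≤ 32, strand-canonical by default) reduced modulo
each table size. Increments touch every table; retrieval takes the minimum.
The counting error is therefore one-sided — a retrieved count is never
below the true count (up to the 255 counter cap) — and the expected false
positive rate for N distinct k-mers is `(1 − exp(−N/H))^Z`, which the
`sizing` module inverts to pick Z and H from a memory budget or a target
rate. The empirical rate (product of table occupancies) is logged after
every run so results at excessive loads can be recognised and discarded.

## Testing

```
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), exact-counter oracles for
the one-sided-error guarantees, and `tests/test_acceptance.py`, which
checks the headline quantitative behaviour (miscount bounds at controlled
false positive rates, sizing optimality, trimming/normalization semantics)
at full fixture scale (~2M distinct 22-mers). The whole run takes a couple
of minutes on one CPU.

## Command line

```
kmersketch count      reads.fq -o counts.cms --k 22 --fp-rate 0.01 --n-kmers 2000000
kmersketch histogram  reads.fq -o hist.tsv   --k 22 --memory 8000000 --n-kmers 2000000
kmersketch error-profile reads.fq -o profile.tsv --tables 100003,100019,100043,100057
kmersketch filter-abund  reads.fq --k 22 --table-size 1000003 --tables-count 4 \
    --cutoff 1 --iterations 6 --report trim.tsv
kmersketch normalize-by-median reads.fq -o kept.fq -C 20 --k 20 \
    --fp-rate 0.01 --n-kmers 2000000
kmersketch synth reads -o sim.fa --length 1000000 --coverage 3 --error-rate 0.03
kmersketch info counts.cms
```

Sketch geometry is resolved with precedence: explicit `--tables` (comma
separated primes) > `--fp-rate` with `--n-kmers` > `--memory` (total
counters) with `--n-kmers`. Inputs are FASTA or FASTQ, plain or
gzip-compressed, auto-detected. Sketches saved with a `.gz` suffix are
gzip-compressed and load transparently.

## Python API

```python
import kmersketch as ks

cfg = ks.KmerConfig(k=22)                      # canonical by default
params = ks.params_for_target_fp(0.01, 2_000_000)
sketch = ks.CountMinSketch(ks.primes_at_or_above(params.h, params.z), cfg)

ks.load_reads_into_sketch("reads.fq.gz", sketch)
hist = ks.abundance_histogram("reads.fq.gz", sketch)
print(sketch.estimate_fp_rate(), hist.as_dict())
```

## Sketch file format

Little-endian: magic `KCMS`, version byte, k, canonical flag, table count
(uint32), total k-mers consumed (uint64), then per table a uint64 size
followed by the raw counter bytes. Gzip is detected by magic on load.
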