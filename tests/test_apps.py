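import numpy as np
import pytest

import kmersketch as ks
from kmersketch.apps import load_reads_into_sketch
from kmersketch.kmer_codec import batch_kmer_hashes
from kmersketch.seqio import ReadRecord
from conftest import exact_counts


def big_sketch(config, h=100_003, z=4):
    return ks.CountMinSketch(ks.primes_at_or_above(h, z), config)


def write_fasta(tmp_path, records, name="reads.fa"):
    path = tmp_path / name
    ks.write_reads(records, str(path), format="fasta")
    return str(path)


class TestAbundanceHistogram:
    def test_single_read_aaaa(self, tmp_path):
        cfg = ks.KmerConfig(k=2)
        path = write_fasta(tmp_path, [ReadRecord(id="r", sequence="AAAA")])
        sk = big_sketch(cfg, h=101, z=2)
        load_reads_into_sketch(path, sk)
        hist = ks.abundance_histogram(path, sk)
        assert hist.as_dict() == {3: 1}
        assert hist.n_distinct == 1
        assert hist.n_total == 3

    def test_twenty_singletons(self, tmp_path):
        cfg = ks.KmerConfig(k=22)
        records = list(ks.random_kmer_reads(20, 22, seed=1))
        path = write_fasta(tmp_path, records)
        sk = big_sketch(cfg)
        load_reads_into_sketch(path, sk)
        hist = ks.abundance_histogram(path, sk)
        assert hist.as_dict() == {1: 20}

    def test_k_mismatch_rejected(self, tmp_path):
        cfg = ks.KmerConfig(k=22)
        path = write_fasta(tmp_path, list(ks.random_kmer_reads(5, 22, seed=2)))
        sk = big_sketch(cfg)
        with pytest.raises(ValueError, match="mismatch"):
            ks.abundance_histogram(path, sk, k=21)

    def test_matches_exact_oracle_at_tiny_fp(self, tmp_path):
        # 10k error-free simulated reads; sketch sized for fp <= 1e-6
        cfg = ks.KmerConfig(k=22)
        genome = ks.random_genome(100_000, seed=3)
        params = ks.SimParams(
            genome_length=len(genome), read_length=100, coverage=10.0, seed=4
        )
        records = list(ks.simulate_reads(genome, params))
        assert len(records) == 10_000
        path = write_fasta(tmp_path, records)
        sized = ks.params_for_target_fp(1e-6, 120_000)
        sk = ks.CountMinSketch(ks.primes_at_or_above(sized.h, sized.z), cfg)
        load_reads_into_sketch(path, sk)
        hist = ks.abundance_histogram(path, sk)
        exact_hist: dict[int, int] = {}
        full_oracle = exact_counts([r.sequence for r in records], cfg)
        for c in full_oracle.values():
            exact_hist[c] = exact_hist.get(c, 0) + 1
        assert hist.as_dict() == exact_hist

    def test_mass_conservation(self, tmp_path):
        cfg = ks.KmerConfig(k=22)
        records = list(ks.random_kmer_reads(500, 22, seed=5))
        path = write_fasta(tmp_path, records)
        sk = big_sketch(cfg)
        load_reads_into_sketch(path, sk)
        hist = ks.abundance_histogram(path, sk)
        assert int(hist.counts.sum()) == hist.n_distinct


class TestPositionProfile:
    def test_duplicated_reads_all_zero(self, tmp_path):
        cfg = ks.KmerConfig(k=8)
        read = ks.random_genome(100, seed=6)
        records = [ReadRecord(id=f"r{i}", sequence=read) for i in range(5)]
        path = write_fasta(tmp_path, records)
        sk = big_sketch(cfg)
        load_reads_into_sketch(path, sk)
        profile = ks.unique_kmer_position_profile(path, sk)
        assert (profile.unique_by_position == 0).all()

    def test_profile_length_for_100bp_k32(self, tmp_path):
        cfg = ks.KmerConfig(k=32)
        genome = ks.random_genome(1000, seed=7)
        params = ks.SimParams(
            genome_length=1000, read_length=100, coverage=3.0, seed=8
        )
        path = write_fasta(tmp_path, list(ks.simulate_reads(genome, params)))
        sk = big_sketch(cfg)
        load_reads_into_sketch(path, sk)
        profile = ks.unique_kmer_position_profile(path, sk)
        assert len(profile.unique_by_position) == 69

    def test_terminal_substitution_lights_up_tail(self, tmp_path):
        # 50 error-free reads at coverage >= 2, plus one read with its last
        # base substituted: unique k-mers only in the final k positions.
        cfg = ks.KmerConfig(k=8)
        genome = ks.random_genome(150, seed=9)
        clean = [
            ReadRecord(id=f"r{i}_{j}", sequence=genome[j : j + 100])
            for i in range(25)
            for j in (0, 50)
        ]
        base = genome[:100]
        flipped = base[:-1] + ("A" if base[-1] != "A" else "C")
        records = clean + [ReadRecord(id="err", sequence=flipped)]
        path = write_fasta(tmp_path, records)
        sk = big_sketch(cfg)
        load_reads_into_sketch(path, sk)
        profile = ks.unique_kmer_position_profile(path, sk)
        n_positions = 100 - 8 + 1
        tail = min(8, n_positions)
        assert (profile.unique_by_position[: n_positions - tail] == 0).all()
        assert profile.unique_by_position[n_positions - tail :].sum() > 0


class TestTrimRead:
    def _sketch_with(self, seqs, cfg):
        sk = big_sketch(cfg, h=10_007, z=4)
        _, _, hashes = batch_kmer_hashes(seqs, cfg)
        sk.update(hashes)
        return sk

    def test_high_abundance_read_unchanged(self):
        cfg = ks.KmerConfig(k=4)
        seq = "ACGTACGTACGT"
        sk = self._sketch_with([seq, seq], cfg)
        read = ReadRecord(id="r", sequence=seq)
        assert ks.trim_read_at_low_abundance(read, sk, cutoff=1) == read

    def test_trim_at_position_five(self):
        # only unique k-mer starts at position 5 with k=4 -> keep 8 bases
        cfg = ks.KmerConfig(k=4, canonical=False)
        backbone = "AAAAAAAAAAAA"  # all k-mers AAAA, highly abundant
        novel = backbone[:5] + "C" + backbone[6:]
        sk = self._sketch_with([backbone] * 10, cfg)
        # load the novel read once: its C-containing k-mers have count 1
        _, _, h = batch_kmer_hashes([novel], cfg)
        sk.update(h)
        trimmed = ks.trim_read_at_low_abundance(
            ReadRecord(id="n", sequence=novel), sk, cutoff=1
        )
        # first k-mer containing the C starts at position 2
        assert trimmed is not None
        assert trimmed.sequence == novel[: 2 + 4 - 1]

    def test_first_kmer_unique_rejects(self):
        cfg = ks.KmerConfig(k=4)
        sk = self._sketch_with(["GGCATTTT"], cfg)
        read = ReadRecord(id="r", sequence="GGCATTTT")
        assert ks.trim_read_at_low_abundance(read, sk, cutoff=1) is None

    def test_quality_truncated_in_lockstep(self):
        cfg = ks.KmerConfig(k=4, canonical=False)
        backbone = "AAAAAAAAAAAA"
        novel = backbone[:5] + "C" + backbone[6:]
        sk = self._sketch_with([backbone] * 10 + [novel], cfg)
        read = ReadRecord(id="n", sequence=novel, quality="ABCDEFGHIJKL")
        trimmed = ks.trim_read_at_low_abundance(read, sk, cutoff=1)
        assert trimmed.quality == "ABCDE"
        assert len(trimmed.quality) == len(trimmed.sequence)

    def test_read_without_kmers_unchanged(self):
        cfg = ks.KmerConfig(k=8)
        sk = big_sketch(cfg, h=101, z=2)
        read = ReadRecord(id="r", sequence="ACGT")
        assert ks.trim_read_at_low_abundance(read, sk, cutoff=1) == read

    def test_never_trims_high_abundance_kmers(self):
        # one-sidedness: k-mers with true abundance > cutoff are never cut
        cfg = ks.KmerConfig(k=6)
        genome = ks.random_genome(500, seed=10)
        reads = [genome[i : i + 60] for i in range(0, 440, 20)] * 3
        oracle = exact_counts(reads, cfg)
        # adversarially tiny sketch: huge fp rate
        sk = ks.CountMinSketch([101, 103], cfg)
        _, _, h = batch_kmer_hashes(reads, cfg)
        sk.update(h)
        cutoff = 2
        for seq in reads[:20]:
            trimmed = ks.trim_read_at_low_abundance(
                ReadRecord(id="r", sequence=seq), sk, cutoff=cutoff
            )
            if trimmed is not None and len(trimmed) < len(seq):
                p = len(trimmed.sequence) - cfg.k + 1
                offending = seq[p : p + cfg.k]
                assert oracle[ks.canonical_hash(offending, cfg)] <= cutoff


class TestIterativeTrim:
    def test_error_free_coverage_two_stops_immediately(self, tmp_path):
        cfg = ks.KmerConfig(k=10)
        genome = ks.random_genome(2000, seed=11)
        records = [
            ReadRecord(id=f"r{i}_{j}", sequence=genome[j : j + 100])
            for i in range(2)
            for j in range(0, 1900, 50)
        ]
        path = write_fasta(tmp_path, records)
        report = ks.iterative_trim(
            path, per_table_size=100_003, z=4, config=cfg,
            cutoff=1, max_iterations=4, output_dir=str(tmp_path / "out"),
        )
        assert len(report.iterations) == 1
        assert report.iterations[0].bases_trimmed_fraction == 0.0

    def test_error_reads_distinct_kmers_decrease(self, tmp_path):
        cfg = ks.KmerConfig(k=22)
        genome = ks.random_genome(50_000, seed=12)
        params = ks.SimParams(
            genome_length=len(genome), read_length=100, coverage=5.0,
            error_rate=0.01, seed=13,
        )
        path = write_fasta(tmp_path, list(ks.simulate_reads(genome, params)))
        report = ks.iterative_trim(
            path, per_table_size=200_003, z=4, config=cfg,
            cutoff=1, max_iterations=4, output_dir=str(tmp_path / "out"),
        )
        distinct = [row.distinct_kmers for row in report.iterations]
        assert all(a >= b for a, b in zip(distinct, distinct[1:]))
        fps = [row.fp_rate for row in report.iterations]
        assert all(a >= b - 1e-9 for a, b in zip(fps, fps[1:]))
        assert report.iterations[0].bases_trimmed_fraction > 0

    def test_high_fp_three_prime_fraction_drops(self, tmp_path):
        # tiny memory -> fp ~ 0.8 in round 1; unique k-mers pile up at the
        # 3' end in round 1 and are cleaned up by round 2
        cfg = ks.KmerConfig(k=22)
        genome = ks.random_genome(50_000, seed=14)
        params = ks.SimParams(
            genome_length=len(genome), read_length=100, coverage=5.0,
            error_rate=0.01, seed=15,
        )
        path = write_fasta(tmp_path, list(ks.simulate_reads(genome, params)))
        report = ks.iterative_trim(
            path, per_table_size=40_009, z=4, config=cfg,
            cutoff=1, max_iterations=3, output_dir=str(tmp_path / "out"),
        )
        assert len(report.iterations) >= 2
        assert report.iterations[0].fp_rate > 0.5
        assert (
            report.iterations[0].unique_at_3prime_fraction
            > report.iterations[1].unique_at_3prime_fraction
        )

    def test_report_tsv(self, tmp_path):
        cfg = ks.KmerConfig(k=10)
        records = list(ks.random_kmer_reads(50, 10, seed=16))
        path = write_fasta(tmp_path, records)
        report = ks.iterative_trim(
            path, per_table_size=10_007, z=2, config=cfg,
            cutoff=1, max_iterations=2, output_dir=str(tmp_path / "out"),
        )
        out = tmp_path / "report.tsv"
        report.write_tsv(str(out))
        lines = out.read_text().splitlines()
        assert lines[0].startswith("iteration\tFP rate")
        assert len(lines) == len(report.iterations) + 1


class TestDigitalNormalize:
    def test_hundred_duplicates_keep_twenty(self, tmp_path):
        cfg = ks.KmerConfig(k=20)
        read = ks.random_genome(100, seed=17)
        records = [ReadRecord(id=f"r{i}", sequence=read) for i in range(100)]
        path = write_fasta(tmp_path, records)
        sk = big_sketch(cfg)
        out = tmp_path / "keep.fa"
        report = ks.digital_normalize(path, sk, coverage=20, output_path=str(out))
        assert report.reads_kept == 20
        assert report.reads_total == 100
        kept = list(ks.stream_reads(str(out)))
        assert [r.id for r in kept] == [f"r{i}" for i in range(20)]

    def test_empty_input(self, tmp_path):
        cfg = ks.KmerConfig(k=20)
        path = tmp_path / "empty.fa"
        path.write_text("")
        sk = big_sketch(cfg)
        out = tmp_path / "keep.fa"
        report = ks.digital_normalize(str(path), sk, coverage=20, output_path=str(out))
        assert report.reads_kept == report.reads_total == 0
        assert list(ks.stream_reads(str(out))) == []

    def test_alternating_disjoint_reads(self, tmp_path):
        cfg = ks.KmerConfig(k=20)
        a = ks.random_genome(100, seed=18)
        b = ks.random_genome(100, seed=19)
        records = []
        for i in range(100):
            records.append(ReadRecord(id=f"a{i}", sequence=a))
            records.append(ReadRecord(id=f"b{i}", sequence=b))
        path = write_fasta(tmp_path, records)
        sk = big_sketch(cfg)
        out = tmp_path / "keep.fa"
        report = ks.digital_normalize(path, sk, coverage=20, output_path=str(out))
        kept = [r.id for r in ks.stream_reads(str(out))]
        assert sum(1 for i in kept if i.startswith("a")) == 20
        assert sum(1 for i in kept if i.startswith("b")) == 20
        assert report.reads_kept == 40

    def test_more_memory_never_fewer_retained(self, tmp_path):
        cfg = ks.KmerConfig(k=20)
        genome = ks.random_genome(2_000, seed=20)
        params = ks.SimParams(
            genome_length=len(genome), read_length=100, coverage=50.0,
            error_rate=0.01, seed=21,
        )
        path = write_fasta(tmp_path, list(ks.simulate_reads(genome, params)))
        retained = []
        for h in (499, 4999, 49999, 499979):
            sk = ks.CountMinSketch(ks.primes_at_or_below(h, 4), cfg)
            out = tmp_path / f"keep_{h}.fa"
            report = ks.digital_normalize(path, sk, coverage=20, output_path=str(out))
            retained.append(report.reads_kept)
        assert retained == sorted(retained)

    def test_deterministic_retained_set(self, tmp_path):
        cfg = ks.KmerConfig(k=20)
        genome = ks.random_genome(1_000, seed=22)
        params = ks.SimParams(
            genome_length=len(genome), read_length=100, coverage=30.0,
            error_rate=0.01, seed=23,
        )
        path = write_fasta(tmp_path, list(ks.simulate_reads(genome, params)))
        kept = []
        for run in range(2):
            sk = big_sketch(cfg)
            out = tmp_path / f"keep_{run}.fa"
            ks.digital_normalize(path, sk, coverage=20, output_path=str(out))
            kept.append([r.id for r in ks.stream_reads(str(out))])
        assert kept[0] == kept[1]

    def test_report_tsv(self, tmp_path):
        cfg = ks.KmerConfig(k=20)
        read = ks.random_genome(100, seed=24)
        path = write_fasta(tmp_path, [ReadRecord(id="r", sequence=read)])
        sk = big_sketch(cfg)
        out = tmp_path / "keep.fa"
        report = ks.digital_normalize(path, sk, coverage=20, output_path=str(out))
        tsv = tmp_path / "norm.tsv"
        report.write_tsv(str(tsv))
        assert tsv.read_text().startswith("FP rate\tretained reads")
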