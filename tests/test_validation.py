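"""Junction depth checks, k-mer QV and homozygous-variant error rate."""

import numpy as np
import pytest
import sympy

from gapmend.genome_io import SequenceRecord
from gapmend.simulate import make_depth_and_kmers, plant_point_errors, random_dna
from gapmend.validation import (
    canonical_kmers,
    decode_kmer,
    encode_kmer,
    homozygous_error_rate,
    junction_coverage,
    kmer_qv,
    kmer_set_of_assembly,
    read_depth_track,
    read_kmer_list,
    write_kmer_list,
)


class TestKmerSets:
    def test_canonical_form(self):
        # a k-mer and its reverse complement encode identically
        assert encode_kmer("ACGTA") == encode_kmer("TACGT")
        assert canonical_kmers("ACGTA", 5).tolist() == canonical_kmers("TACGT", 5).tolist()

    def test_kmers_skip_n(self):
        # windows touching the N are dropped; the two ACG copies collapse to one
        assert canonical_kmers("ACGNACG", 3).size == 1

    def test_decode_round_trip(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 300)
        k = 21
        kmers = canonical_kmers(seq, k)
        for v in kmers[:20]:
            assert encode_kmer(decode_kmer(int(v), k)) == int(v)

    def test_kmer_list_file_round_trip(self, tmp_path):
        seq = random_dna(np.random.default_rng(5), 500)
        kmers = canonical_kmers(seq, 21)
        p = tmp_path / "kmers.txt"
        write_kmer_list(kmers, 21, p)
        assert read_kmer_list(p, 21).tolist() == kmers.tolist()


class TestKmerQV:
    def test_full_sharing_hits_cap(self):
        a = np.arange(50, dtype=np.int64)
        est = kmer_qv(a, a, 21, qv_cap=99.0)
        assert est.qv == 99.0
        assert est.per_base_error == 0.0

    def test_closed_form_k1(self):
        a = np.arange(10, dtype=np.int64)
        est = kmer_qv(a, a[:9], 1)
        assert est.per_base_error == pytest.approx(0.1)
        assert est.qv == pytest.approx(10.0)

    def test_half_shared_k21_against_arbitrary_precision(self):
        # oracle: error = 1 - 0.5**(1/21); qv = -10*log10(error), at 50 digits
        err = 1 - sympy.Rational(1, 2) ** sympy.Rational(1, 21)
        expected = float(-10 * sympy.log(err, 10).evalf(50))
        a = np.arange(100, dtype=np.int64)
        est = kmer_qv(a, a[:50], 21)
        assert est.qv == pytest.approx(expected, abs=1e-6)
        assert est.qv == pytest.approx(14.88, abs=0.01)

    def test_qv_strictly_decreasing_in_assembly_only_kmers(self):
        rng = np.random.default_rng(6)
        reads = np.unique(rng.integers(0, 10**9, size=2000).astype(np.int64))
        base = reads[:500]
        extras = np.setdiff1d(
            np.unique(rng.integers(10**9, 2 * 10**9, size=200).astype(np.int64)), reads
        )
        qvs = []
        for n_extra in (0, 5, 20, 50, 100):
            asm = np.concatenate([base, extras[:n_extra]])
            qvs.append(kmer_qv(asm, reads, 21).qv)
        assert all(a > b for a, b in zip(qvs, qvs[1:]))

    def test_empty_assembly_set_is_error(self):
        with pytest.raises(ValueError, match="no k-mers"):
            kmer_qv(np.empty(0, dtype=np.int64), np.arange(5, dtype=np.int64), 21)

    def test_planted_errors_recovered_within_20_percent(self):
        genome = [SequenceRecord("c", random_dna(np.random.default_rng(7), 200_000))]
        k = 21
        m = 50
        mutated, positions = plant_point_errors(genome, m, seed=8, min_spacing=200)
        _, read_kmers = make_depth_and_kmers(genome, k=k)
        asm_kmers = kmer_set_of_assembly(mutated, k)
        est = kmer_qv(asm_kmers, read_kmers, k)
        true_rate = m / 200_000
        assert est.per_base_error == pytest.approx(true_rate, rel=0.2)


class TestJunctionCoverage:
    def test_constant_depth_passes(self):
        depth = {"c": np.full(1000, 30)}
        (check,) = junction_coverage(depth, [("c", 500)], window=50, min_depth=1)
        assert check.passed and check.observed_min == 30

    def test_zero_depth_base_fails(self):
        track = np.full(1000, 30)
        track[520] = 0
        (check,) = junction_coverage({"c": track}, [("c", 500)], window=50, min_depth=1)
        assert not check.passed

    def test_window_clipped_at_chromosome_start(self):
        track = np.full(1000, 5)
        track[0] = 7  # clipped window must not look left of 0
        (check,) = junction_coverage({"c": track}, [("c", 10)], window=50, min_depth=1)
        # evaluated over [0, 60]
        assert check.observed_min == 5
        assert check.passed

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(KeyError):
            junction_coverage({"c": np.zeros(10)}, [("x", 1)])

    def test_depth_track_formats(self, tmp_path):
        samtools = tmp_path / "d.tsv"
        samtools.write_text("c\t1\t7\nc\t2\t9\n")
        track = read_depth_track(samtools, {"c": 3})
        assert track["c"].tolist() == [7, 9, 0]
        bedgraph = tmp_path / "d.bg"
        bedgraph.write_text("c\t0\t2\t5\nc\t2\t3\t1\n")
        track = read_depth_track(bedgraph, {"c": 3})
        assert track["c"].tolist() == [5, 5, 1]


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=c,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
"""


def _vcf_line(pos, qual, gt, dp=30):
    return f"c\t{pos}\tv{pos}\tA\tG\t{qual}\tPASS\t.\tGT:DP\t{gt}:{dp}\n"


class TestHomozygousErrorRate:
    def test_hand_counted_mixed_fixture(self, tmp_path):
        # 5 homozygous-alt + 3 het, all passing filters
        lines = [_vcf_line(100 * (i + 1), 60, "1/1") for i in range(5)]
        lines += [_vcf_line(1000 * (i + 1) + 7, 60, "0/1") for i in range(3)]
        p = tmp_path / "calls.vcf"
        p.write_text(VCF_HEADER + "".join(lines))
        est = homozygous_error_rate(p, assembly_size=10**6)
        assert est.homozygous_variants == 5
        assert est.rate == pytest.approx(5e-6)

    def test_only_het_gives_zero(self, tmp_path):
        p = tmp_path / "calls.vcf"
        p.write_text(VCF_HEADER + _vcf_line(10, 60, "0/1") + _vcf_line(20, 60, "0|1"))
        assert homozygous_error_rate(p, 10**6).rate == 0.0

    def test_rate_arithmetic(self, tmp_path):
        p = tmp_path / "calls.vcf"
        p.write_text(VCF_HEADER + _vcf_line(10, 60, "1/1") + _vcf_line(20, 60, "1|1"))
        est = homozygous_error_rate(p, assembly_size=10**6)
        assert est.rate == pytest.approx(2e-6)

    def test_quality_and_depth_filters(self, tmp_path):
        p = tmp_path / "calls.vcf"
        p.write_text(
            VCF_HEADER
            + _vcf_line(10, 10, "1/1")  # low QUAL
            + _vcf_line(20, 60, "1/1", dp=2)  # low depth
            + _vcf_line(30, 60, "1/1")
        )
        est = homozygous_error_rate(p, 10**6, min_qual=30, min_depth=5)
        assert est.homozygous_variants == 1

    def test_missing_gt_skipped_with_count(self, tmp_path):
        p = tmp_path / "calls.vcf"
        p.write_text(
            VCF_HEADER + "c\t10\tv\tA\tG\t60\tPASS\t.\tGT:DP\t./.:30\n"
            + _vcf_line(30, 60, "1/1")
        )
        est = homozygous_error_rate(p, 10**6)
        assert est.homozygous_variants == 1
        assert est.skipped_no_gt == 1
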