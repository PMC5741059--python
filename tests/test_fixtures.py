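"""The synthetic-data generator itself."""

import filecmp

import pysam
import pytest

from svbreakend._util import revcomp
from svbreakend.fixtures import (
    SVSpec,
    generate_genome,
    plant_svs,
    reference_haplotype,
    simulate_reads,
    write_fasta,
    write_truth_bedpe,
)


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        assert generate_genome(2000, 0.4, seed=3) == generate_genome(2000, 0.4, seed=3)

    def test_gc_zero_uses_only_at(self):
        seq = generate_genome(2000, 0.0, seed=3)["chr1"]
        assert set(seq) <= {"A", "T"}

    def test_gc_fraction_within_binomial_bound(self):
        n = 100_000
        seq = generate_genome(n, 0.5, seed=4)["chr1"]
        gc = sum(b in "GC" for b in seq) / n
        assert abs(gc - 0.5) <= 3 * (0.25 / n) ** 0.5

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            generate_genome(100)


@pytest.fixture(scope="module")
def genome30k():
    return generate_genome(30_000, 0.5, seed=5)


class TestPlantSvs:
    @pytest.fixture
    def genome(self, genome30k):
        return genome30k

    def test_deletion_shrinks_genome(self, genome):
        hap, truth = plant_svs(genome, [SVSpec("DEL", "chr1", 10_000, size=500)])
        assert len(hap.contigs["chr1"]) == 30_000 - 500
        assert truth[0].junction.pos_l == 9999
        assert truth[0].junction.pos_h == 10_500

    def test_tandem_duplication_grows_genome(self, genome):
        hap, _ = plant_svs(genome, [SVSpec("DUP", "chr1", 10_000, size=1000)])
        assert len(hap.contigs["chr1"]) == 31_000
        s = genome["chr1"][9999:10_999]
        assert hap.contigs["chr1"][9999:11_999] == s + s

    def test_inversion_reverse_complements_segment(self, genome):
        hap, truth = plant_svs(genome, [SVSpec("INV", "chr1", 10_000, size=2000)])
        assert len(hap.contigs["chr1"]) == 30_000
        assert hap.contigs["chr1"][9999:11_999] == revcomp(
            genome["chr1"][9999:11_999]
        )
        assert len(truth) == 2  # two junctions

    def test_insertion_records_untemplated_sequence(self, genome):
        hap, truth = plant_svs(
            genome, [SVSpec("INS", "chr1", 10_000, ins_seq="GATTACA")]
        )
        assert len(hap.contigs["chr1"]) == 30_007
        assert truth[0].untemplated_seq == "GATTACA"

    def test_overlapping_events_error(self, genome):
        with pytest.raises(ValueError, match="overlap"):
            plant_svs(
                genome,
                [
                    SVSpec("DEL", "chr1", 10_000, size=500),
                    SVSpec("DUP", "chr1", 10_200, size=100),
                ],
            )

    def test_planted_homology_rederived_by_direct_scan(self, genome):
        # engineer 4 identical bases after both junction sides, then check the
        # truth record recovers homology length 4 by an independent scan
        seq = list(genome["chr1"])
        p, size = 10_000, 500
        q = p + size  # first retained base after the deletion, 0-based q
        for i in range(4):
            seq[q + i] = seq[p + i]
        if seq[q + 4] == seq[p + 4]:
            seq[q + 4] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p + 4]]
        if seq[q - 1] == seq[p - 1]:
            seq[q - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p - 1]]
        mod = {"chr1": "".join(seq)}
        hap, truth = plant_svs(mod, [SVSpec("DEL", "chr1", p + 1, size=size)])
        assert truth[0].homology_len == 4
        # independent scan on the mutated sequence: sliding the junction
        der = mod["chr1"][:p] + mod["chr1"][q:]
        slid = 0
        for s in range(1, 10):
            if mod["chr1"][: p + s] + mod["chr1"][q + s :] == der:
                slid = s
            else:
                break
        assert slid == 4

    def test_translocation_moves_suffix(self):
        g = {
            **generate_genome(10_000, 0.5, seed=6, name="chrA"),
            **generate_genome(10_000, 0.5, seed=7, name="chrB"),
        }
        hap, truth = plant_svs(
            g, [SVSpec("TRA", "chrA", 4000, contig2="chrB", pos2=6000)]
        )
        assert hap.contigs["chrA"] == g["chrA"][:4000] + g["chrB"][5999:]
        assert hap.contigs["chrB"] == g["chrB"][:5999]
        j = truth[0].junction
        assert (j.contig_l, j.pos_l, j.dir_l) == ("chrA", 4000, "+")
        assert (j.contig_h, j.pos_h, j.dir_h) == ("chrB", 6000, "-")


@pytest.fixture(scope="module")
def genome10k():
    return generate_genome(10_000, 0.5, seed=8)


class TestSimulateReads:
    @pytest.fixture
    def genome(self, genome10k):
        return genome10k

    def test_error_free_reads_substring_match_their_haplotype(self, genome, tmp_path):
        sam = str(tmp_path / "clean.sam")
        simulate_reads(
            [reference_haplotype(genome)], genome, sam, coverage=5,
            error_rate=0.0, seed=9,
        )
        seq = genome["chr1"]
        with pysam.AlignmentFile(sam) as fh:
            for read in fh:
                assert read.query_sequence in seq

    def test_read_count_matches_coverage_arithmetic(self, genome, tmp_path):
        sam = str(tmp_path / "count.sam")
        n = simulate_reads(
            [reference_haplotype(genome)], genome, sam, coverage=10,
            read_len=100, seed=10,
        )
        expected = round(10 * 10_000 / (2 * 100))
        assert abs(n - expected) <= 1

    def test_fixed_seed_gives_byte_identical_output(self, genome, tmp_path):
        a, b = str(tmp_path / "a.sam"), str(tmp_path / "b.sam")
        for path in (a, b):
            simulate_reads(
                [reference_haplotype(genome)], genome, path, coverage=4, seed=11
            )
        assert filecmp.cmp(a, b, shallow=False)

    def test_coverage_must_be_positive(self, genome, tmp_path):
        with pytest.raises(ValueError):
            simulate_reads(
                [reference_haplotype(genome)], genome, str(tmp_path / "x.sam"),
                coverage=0,
            )

    def test_junction_reads_emitted_soft_clipped_at_reference_position(
        self, genome, tmp_path
    ):
        hap, truth = plant_svs(genome, [SVSpec("DEL", "chr1", 5000, size=500)])
        sam = str(tmp_path / "del.sam")
        simulate_reads([hap], genome, sam, coverage=30, error_rate=0.0, seed=12)
        clipped = []
        with pysam.AlignmentFile(sam) as fh:
            for read in fh:
                if read.is_unmapped or not read.cigartuples:
                    continue
                if any(op == 4 for op, _ in read.cigartuples):
                    clipped.append(read)
        assert clipped
        # every right-clipped read's aligned block must end at the junction
        for read in clipped:
            ops = read.cigartuples
            if ops[-1][0] == 4 and ops[0][0] == 0:
                assert read.reference_end == 4999
            if ops[0][0] == 4 and ops[-1][0] == 0:
                assert read.reference_start == 5499

    def test_truth_bedpe_written(self, genome, tmp_path):
        _, truth = plant_svs(genome, [SVSpec("DEL", "chr1", 5000, size=500)])
        path = str(tmp_path / "truth.bedpe")
        write_truth_bedpe(truth, path)
        lines = [l for l in open(path) if not l.startswith("#")]
        assert len(lines) == 1
        assert lines[0].split("\t")[0] == "chr1"

    def test_write_fasta_faidx_compatible(self, genome, tmp_path):
        import pyfaidx

        path = str(tmp_path / "ref.fasta")
        write_fasta(genome, path)
        fa = pyfaidx.Fasta(path)
        assert str(fa["chr1"]) == genome["chr1"]
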