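"""Read classification, evidence extraction, split-read identification."""

import pysam
import pytest

from svbreakend.align import SeedAligner
from svbreakend.evidence import (
    EvidenceKind,
    classify_read,
    extract_evidence,
    identify_split_reads,
)
from svbreakend.fixtures import (
    SVSpec,
    generate_genome,
    plant_svs,
    reference_haplotype,
    simulate_reads,
)
from svbreakend.metrics import collect_metrics

from conftest import make_fr_pair, make_header, sam_pair_line, write_sam


def segment(line, contigs=None):
    header = make_header(contigs)
    return pysam.AlignedSegment.fromstring(line, header)


@pytest.fixture
def metrics(tmp_path):
    lines = []
    for i in range(200):
        lines.extend(make_fr_pair(f"p{i}", "chr1", 1000 + 11 * i, 280 + (i % 41)))
    lines.sort(key=lambda l: int(l.split("\t")[3]))
    return collect_metrics(write_sam(tmp_path / "lib.sam", lines))


class TestClassify:
    def test_concordant_pair_is_nothing(self, metrics):
        read = segment(
            sam_pair_line("r", 99, "chr1", 1000, 60, "100M", 1200, 300, "A" * 100,
                          tags=("MC:Z:100M",))
        )
        assert classify_read(read, metrics) == set()

    def test_soft_clip_is_definitional(self, metrics):
        read = segment(
            sam_pair_line("r", 99, "chr1", 1000, 60, "50M50S", 1200, 300, "A" * 100,
                          tags=("MC:Z:100M",))
        )
        assert classify_read(read, metrics) == {EvidenceKind.SOFT_CLIP}

    def test_unmapped_mate_is_one_end_anchor(self, metrics):
        read = segment(
            sam_pair_line("r", 0x1 | 0x8 | 0x40, "chr1", 1000, 60, "100M", 1000, 0, "A" * 100)
        )
        assert classify_read(read, metrics) == {EvidenceKind.ONE_END_ANCHOR}

    def test_both_unmapped_pair_is_nothing(self, metrics):
        read = segment(
            sam_pair_line("r", 0x1 | 0x4 | 0x8 | 0x40, "chr1", 1000, 0, "*", 1000, 0, "A" * 100)
        )
        assert classify_read(read, metrics) == set()

    def test_long_fragment_is_discordant(self, metrics):
        read = segment(
            sam_pair_line("r", 99, "chr1", 1000, 60, "100M", 1900, 1000, "A" * 100,
                          tags=("MC:Z:100M",))
        )
        assert classify_read(read, metrics) == {EvidenceKind.DISCORDANT_PAIR}

    def test_wrong_orientation_is_discordant(self, metrics):
        # both reads forward (mate-reverse flag unset)
        read = segment(
            sam_pair_line("r", 0x1 | 0x40, "chr1", 1000, 60, "100M", 1200, 300, "A" * 100)
        )
        assert classify_read(read, metrics) == {EvidenceKind.DISCORDANT_PAIR}

    def test_indel_cigar(self, metrics):
        read = segment(
            sam_pair_line("r", 99, "chr1", 1000, 60, "40M10D60M", 1200, 300, "A" * 100,
                          tags=("MC:Z:100M",))
        )
        assert classify_read(read, metrics) == {EvidenceKind.INDEL}

    def test_duplicate_reads_dropped(self, metrics):
        read = segment(
            sam_pair_line("r", 99 | 0x400, "chr1", 1000, 60, "50M50S", 1200, 300, "A" * 100)
        )
        assert classify_read(read, metrics) == set()

    def test_pure(self, metrics):
        read = segment(
            sam_pair_line("r", 99, "chr1", 1000, 60, "50M50S", 1900, 1000, "A" * 100,
                          tags=("MC:Z:100M",))
        )
        assert classify_read(read, metrics) == classify_read(read, metrics)


class TestExtract:
    def test_concordant_only_input_gives_empty_stream(self, tmp_path, metrics):
        lines = []
        for i in range(20):
            lines.extend(make_fr_pair(f"c{i}", "chr1", 2000 + 13 * i, 300))
        lines.sort(key=lambda l: int(l.split("\t")[3]))
        path = write_sam(tmp_path / "conc.sam", lines)
        assert extract_evidence([path], [metrics]) == []

    def test_indel_and_clip_records_from_one_read(self, tmp_path, metrics):
        line = sam_pair_line("r", 0, "chr1", 1000, 60, "30M2D30S", 1000, 0, "A" * 60)
        path = write_sam(tmp_path / "mix.sam", [line])
        evidence = extract_evidence([path], [metrics])
        kinds = sorted(ev.kind for ev in evidence)
        assert kinds == [EvidenceKind.INDEL, EvidenceKind.SOFT_CLIP]
        indel = next(ev for ev in evidence if ev.kind is EvidenceKind.INDEL)
        assert (indel.indel_op, indel.indel_len) == ("D", 2)
        assert indel.locus_a.pos == 1029  # last aligned base before the op
        clip = next(ev for ev in evidence if ev.kind is EvidenceKind.SOFT_CLIP)
        assert clip.clip_side == "R" and clip.l_sc == 30

    def test_short_or_low_quality_clips_filtered(self, tmp_path, metrics):
        q_low = chr(3 + 33) * 60
        lines = [
            sam_pair_line("short", 0, "chr1", 1000, 60, "57M3S", 1000, 0, "A" * 60),
            sam_pair_line("lowq", 0, "chr1", 2000, 60, "30M30S", 2000, 0, "A" * 60,
                          qual=q_low),
        ]
        path = write_sam(tmp_path / "filters.sam", lines)
        assert extract_evidence([path], [metrics]) == []

    def test_unsorted_input_names_offending_record(self, tmp_path, metrics):
        lines = [
            sam_pair_line("a", 0, "chr1", 5000, 60, "50M10S", 5000, 0, "A" * 60),
            sam_pair_line("zzz", 0, "chr1", 1000, 60, "50M10S", 1000, 0, "A" * 60),
        ]
        path = write_sam(tmp_path / "unsorted.sam", lines)
        with pytest.raises(ValueError, match="zzz"):
            extract_evidence([path], [metrics])

    def test_stream_ordered_by_locus(self, tmp_path, metrics):
        lines = [
            sam_pair_line("a", 0, "chr1", 1000, 60, "50M10S", 1000, 0, "A" * 60),
            sam_pair_line("b", 0, "chr1", 3000, 60, "10S50M", 3000, 0, "A" * 60),
        ]
        path = write_sam(tmp_path / "ord.sam", lines)
        evidence = extract_evidence([path], [metrics])
        keys = [(ev.locus_a.contig, ev.locus_a.pos) for ev in evidence]
        assert keys == sorted(keys)

    def test_dp_count_matches_brute_force_on_planted_deletion(self, tmp_path):
        genome = generate_genome(30_000, 0.5, seed=5)
        hap, _ = plant_svs(genome, [SVSpec("DEL", "chr1", 15_000, size=500)], seed=5)
        sam = str(tmp_path / "del.sam")
        simulate_reads(
            [reference_haplotype(genome), hap], genome, sam, coverage=30, seed=6
        )
        m = collect_metrics(sam)
        evidence = extract_evidence([sam], [m])
        n_dp_pairs = sum(
            1
            for ev in evidence
            if ev.kind is EvidenceKind.DISCORDANT_PAIR and ev.pair_representative
        )
        # independent brute-force scan of the alignment file
        oracle = 0
        with pysam.AlignmentFile(sam) as fh:
            for read in fh:
                if read.is_unmapped or read.mate_is_unmapped or not read.is_read1:
                    continue
                if read.is_reverse or not read.mate_is_reverse:
                    # simulator emits FR pairs; anything else would be discordant
                    oracle += 1
                    continue
                mate_cig = read.get_tag("MC")
                mate_span = sum(
                    int(n) for n, op in _cig_ops(mate_cig) if op in "MDN=X"
                )
                ifs = (read.next_reference_start + mate_span) - read.reference_start
                if not (m.concordant_lo <= ifs <= m.concordant_hi):
                    oracle += 1
        assert n_dp_pairs == oracle
        assert oracle > 0


def _cig_ops(cig):
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


class TestSplitReads:
    class FixedAligner:
        def __init__(self, hit):
            self.hit = hit

        def align(self, query):
            return self.hit

    def test_low_mapq_realignment_stays_soft_clip(self, tmp_path, metrics):
        from svbreakend.align import Hit

        line = sam_pair_line("r", 0, "chr1", 1000, 60, "30M30S", 1000, 0, "A" * 60)
        ev = extract_evidence([write_sam(tmp_path / "sc.sam", [line])], [metrics])
        hit = Hit("chr1", 5000, 5029, "+", 0, 30, score=30, mapq=5.0)
        out = identify_split_reads(ev, self.FixedAligner(hit), min_mapq=10)
        assert [e.kind for e in out] == [EvidenceKind.SOFT_CLIP]

    def test_unique_clip_becomes_split_read(self, tmp_path):
        genome = generate_genome(10_000, 0.5, seed=9)
        ref = genome["chr1"]
        # read: 30 bases anchored at 1001 + 40 clipped bases from 5001
        seq = ref[1000:1030] + ref[5000:5040]
        line = sam_pair_line("r", 0, "chr1", 1001, 60, "30M40S", 1001, 0, seq)
        path = write_sam(tmp_path / "sr.sam", [line], contigs={"chr1": 10_000})
        m = collect_metrics(path)
        evidence = extract_evidence([path], [m])
        out = identify_split_reads(evidence, SeedAligner(genome), min_mapq=10)
        (sr,) = out
        assert sr.kind is EvidenceKind.SPLIT_READ
        assert (sr.locus_a.pos, sr.locus_a.direction) == (1030, "+")
        assert (sr.locus_b.contig, sr.locus_b.pos, sr.locus_b.direction) == (
            "chr1", 5001, "-",
        )
        assert sr.untemplated_seq == ""

    def test_indel_read_becomes_junction_spanning_split_read(self, tmp_path, metrics):
        line = sam_pair_line("r", 0, "chr1", 1001, 60, "30M100D30M", 1001, 0, "A" * 60)
        path = write_sam(tmp_path / "indel.sam", [line])
        evidence = extract_evidence([path], [metrics])
        out = identify_split_reads(evidence, self.FixedAligner(None))
        sr = next(e for e in out if e.kind is EvidenceKind.SPLIT_READ)
        assert (sr.locus_a.pos, sr.locus_a.direction) == (1030, "+")
        assert (sr.locus_b.pos, sr.locus_b.direction) == (1131, "-")
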