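"""Contig realignment into breakpoint evidence."""

import pytest

from svbreakend.align import SeedAligner
from svbreakend.assembly import BreakendContig
from svbreakend.evidence import EvidenceKind, Locus, ReadEvidence
from svbreakend.fixtures import generate_genome
from svbreakend.realign import (
    discordant_pair_to_breakpoint,
    realign_contig,
    split_read_to_breakpoint,
)

from conftest import stub_metrics


@pytest.fixture(scope="module")
def ref():
    return generate_genome(12_000, 0.5, seed=41)


@pytest.fixture(scope="module")
def aligner(ref):
    return SeedAligner(ref)


def sc_constituent(mapq=55.0):
    return ReadEvidence(
        kind=EvidenceKind.SOFT_CLIP,
        read_id="c1",
        library_id="stub",
        category="default",
        locus_a=Locus("chr1", 1030, "+"),
        l_sc=20,
        mapq_a=mapq,
    )


def make_contig(ref, direction, anchored, unanchored, anchor_pos, support=None):
    return BreakendContig(
        direction=direction,
        contig="chr1",
        anchored_seq=anchored,
        unanchored_seq=unanchored,
        anchor_pos=anchor_pos,
        support=support or {"c1", "c2", "c3"},
        total_weight=100,
    )


class TestRealignContig:
    def test_simple_junction(self, ref, aligner):
        seq = ref["chr1"]
        contig = make_contig(ref, "fwd", seq[1000:1030], seq[5000:5030], 1030)
        bps, singles = realign_contig(
            contig, ref, aligner, stub_metrics(sc_tail=0.01), [sc_constituent()]
        )
        assert not singles
        (bp,) = bps
        assert (bp.contig_l, bp.d_l) == ("chr1", "+")
        assert bp.s_l <= 1030 <= bp.e_l
        assert (bp.contig_h, bp.d_h) == ("chr1", "-")
        assert bp.s_h <= 5001 <= bp.e_h
        assert bp.origin == "ASSEMBLY"
        assert bp.exact and (bp.nominal_l, bp.nominal_h) == (1030, 5001)

    def test_backward_contig_junction(self, ref, aligner):
        from svbreakend._util import revcomp

        seq = ref["chr1"]
        # '-' break-end at 5001 joined to a '+' partner at 1030: in junction
        # orientation the anchor reads genome-reverse from 5030 down to 5001
        anchored = revcomp(seq[5000:5030])
        unanchored = revcomp(seq[1000:1030])
        contig = make_contig(ref, "bwd", anchored, unanchored, 5001)
        bps, _ = realign_contig(
            contig, ref, aligner, stub_metrics(sc_tail=0.01), [sc_constituent()]
        )
        (bp,) = bps
        assert (bp.d_l, bp.d_h) == ("+", "-")
        assert (bp.nominal_l, bp.nominal_h) == (1030, 5001)

    def test_fully_reference_contig_discarded(self, ref, aligner):
        seq = ref["chr1"]
        contig = make_contig(ref, "fwd", seq[1000:1040], seq[1040:1060], 1040)
        bps, singles = realign_contig(
            contig, ref, aligner, stub_metrics(sc_tail=0.01), [sc_constituent()]
        )
        assert bps == [] and singles == []

    def test_compound_realignment_emits_chain_of_junctions(self, ref, aligner):
        seq = ref["chr1"]
        a = seq[1000:1060]
        c = seq[3000:3040]
        b = seq[7000:7040]
        contig = make_contig(ref, "fwd", a, c + b, 1060)
        bps, singles = realign_contig(
            contig, ref, aligner, stub_metrics(sc_tail=0.01), [sc_constituent()]
        )
        assert len(bps) == 2
        bps.sort(key=lambda bp: bp.s_l)
        first, second = bps
        assert (first.nominal_l, first.nominal_h) == (1060, 3001)
        assert (second.nominal_l, second.nominal_h) == (3040, 7001)
        # query bases consumed disjointly along the chain
        assert not singles

    def test_depth_limit_produces_single_breakend(self, ref, aligner):
        seq = ref["chr1"]
        a = seq[1000:1060]
        residue = "TTTT" * 10  # aligns nowhere in a random genome
        contig = make_contig(ref, "fwd", a, residue, 1060)
        bps, singles = realign_contig(
            contig, ref, aligner, stub_metrics(sc_tail=0.01), [sc_constituent()]
        )
        assert bps == []
        (sb,) = singles
        assert (sb.contig, sb.pos, sb.direction) == ("chr1", 1060, "+")
        assert sb.inserted_seq == residue

    def test_small_deletion_spanning_contig_yields_indel_junction(self, ref, aligner):
        seq = ref["chr1"]
        # 5-base deletion with long matching flanks: full-length SW alignment
        contig_seq = seq[2000:2060] + seq[2065:2125]
        contig = make_contig(ref, "fwd", contig_seq[:60], contig_seq[60:], 2060)
        bps, _ = realign_contig(
            contig, ref, aligner, stub_metrics(sc_tail=0.01), [sc_constituent()]
        )
        (bp,) = bps
        assert (bp.nominal_l, bp.nominal_h) == (2060, 2066)
        assert (bp.d_l, bp.d_h) == ("+", "-")


class TestDirectEvidence:
    def test_split_read_rectangle_widened_by_homology(self, ref):
        ev = ReadEvidence(
            kind=EvidenceKind.SPLIT_READ,
            read_id="r/1",
            library_id="stub",
            category="default",
            locus_a=Locus("chr1", 1030, "+"),
            locus_b=Locus("chr1", 5001, "-"),
            l_sc=40,
            mapq_a=60.0,
            mapq_b=60.0,
        )
        bp = split_read_to_breakpoint(ev, ref, stub_metrics(sc_tail=0.01))
        assert bp.origin == "SR"
        assert bp.exact
        assert bp.s_l <= 1030 <= bp.e_l
        assert (bp.e_l - bp.s_l) == (bp.e_h - bp.s_h)  # both sides share homlen

    def test_discordant_pair_rectangle_geometry(self):
        m = stub_metrics(p_d=0.01, rp_tail=0.001, concordant=(250, 350))
        ev = ReadEvidence(
            kind=EvidenceKind.DISCORDANT_PAIR,
            read_id="r/1",
            library_id="stub",
            category="default",
            locus_a=Locus("chr1", 1100, "+"),
            ifs=900,
            mapq_a=60.0,
            mapq_b=60.0,
            seq="A" * 100,
            aln_ref_start=1001,
            aln_ref_end=1100,
            strand="+",
            mate_contig="chr1",
            mate_start=1801,
            mate_end=1900,
            mate_strand="-",
        )
        bp = discordant_pair_to_breakpoint(ev, m)
        # '+' side: [last aligned base, start + hi - 1 - mate_len]
        assert (bp.s_l, bp.e_l) == (1100, 1001 + 350 - 1 - 100)
        assert (bp.d_l, bp.d_h) == ("+", "-")
        # '-' side: [end - hi + 1 + own_len, first aligned base]
        assert (bp.s_h, bp.e_h) == (1900 - 350 + 1 + 100, 1801)

    def test_non_representative_pair_record_skipped(self):
        m = stub_metrics()
        ev = ReadEvidence(
            kind=EvidenceKind.DISCORDANT_PAIR,
            read_id="r/2",
            library_id="stub",
            category="default",
            locus_a=Locus("chr1", 1900, "-"),
            mapq_a=60.0,
            pair_representative=False,
        )
        assert discordant_pair_to_breakpoint(ev, m) is None
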