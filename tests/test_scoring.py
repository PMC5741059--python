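"""The Phred-scaled evidence scoring model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svbreakend.evidence import EvidenceKind, Locus, ReadEvidence
from svbreakend.scoring import (
    kmer_weight,
    phred,
    promote_constituent,
    score_assembly,
    score_indel_read,
    score_read_pair,
    score_split_read,
    unphred,
)

from conftest import stub_metrics


def _evidence(kind, mapq_a=60.0, mapq_b=None, l_sc=10, ifs=None, indel_op=None,
              indel_len=0):
    return ReadEvidence(
        kind=kind,
        read_id="r1",
        library_id="stub",
        category="default",
        locus_a=Locus("chr1", 100, "+"),
        locus_b=Locus("chr1", 500, "-") if mapq_b is not None else None,
        l_sc=l_sc,
        ifs=ifs,
        mapq_a=mapq_a,
        mapq_b=mapq_b,
        indel_op=indel_op,
        indel_len=indel_len,
    )


class TestPhred:
    @pytest.mark.parametrize("p,q", [(1.0, 0.0), (0.1, 10.0), (0.001, 30.0)])
    def test_known_values(self, p, q):
        assert phred(p) == pytest.approx(q, abs=1e-9)

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_out_of_range(self, p):
        with pytest.raises(ValueError):
            phred(p)

    def test_cap(self):
        assert phred(0.0) == 100.0
        assert phred(1e-30) == 100.0

    @given(st.floats(min_value=1e-9, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity_below_cap(self, p):
        assert unphred(phred(p)) == pytest.approx(p, rel=1e-9)


class TestKmerWeight:
    def test_mapq_zero_gives_zero(self):
        assert kmer_weight(0.0, [30, 30, 30], 0, 3) == pytest.approx(0.0, abs=1e-12)

    def test_single_base(self):
        # 1 - 0.9 * 0.9 = 0.19
        w = kmer_weight(10.0, [10], 0, 1)
        assert w == pytest.approx(-10 * math.log10(0.19), abs=1e-9)
        assert w == pytest.approx(7.2124639904717, abs=1e-6)

    def test_two_bases(self):
        w = kmer_weight(30.0, [20, 20], 0, 2)
        expected = -10 * math.log10(1 - 0.999 * 0.99**2)
        assert w == pytest.approx(expected, abs=1e-9)
        assert w == pytest.approx(16.8029, abs=1e-3)

    def test_out_of_bounds(self):
        with pytest.raises(IndexError):
            kmer_weight(30.0, [20, 20], 1, 2)

    @given(st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_mapq(self, q1, q2):
        lo, hi = sorted((q1, q2))
        quals = [25, 25, 25, 25]
        assert kmer_weight(hi, quals, 0, 4) >= kmer_weight(lo, quals, 0, 4)


class TestSplitReadScore:
    def test_mapq_zero(self):
        ev = _evidence(EvidenceKind.SPLIT_READ, mapq_a=0.0, mapq_b=0.0)
        assert score_split_read(ev, stub_metrics(sc_tail=0.01)).q == pytest.approx(0.0)

    def test_full_tail_mass(self):
        ev = _evidence(EvidenceKind.SPLIT_READ, mapq_a=40.0, mapq_b=40.0)
        assert score_split_read(ev, stub_metrics(sc_tail=1.0)).q == pytest.approx(0.0)

    def test_certain_mapping(self):
        ev = _evidence(EvidenceKind.SPLIT_READ, mapq_a=100.0, mapq_b=100.0)
        q = score_split_read(ev, stub_metrics(sc_tail=0.01)).q
        assert q == pytest.approx(20.0, abs=1e-6)

    def test_soft_clip_uses_single_locus(self):
        # a bare soft clip must not be penalised for a missing second mapq
        ev = _evidence(EvidenceKind.SOFT_CLIP, mapq_a=100.0)
        q = score_split_read(ev, stub_metrics(sc_tail=0.1)).q
        assert q == pytest.approx(10.0, abs=1e-6)

    @given(st.floats(1e-4, 1.0), st.floats(1e-4, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_tail_mass(self, m1, m2):
        lo, hi = sorted((m1, m2))
        ev = _evidence(EvidenceKind.SPLIT_READ, mapq_a=40.0, mapq_b=40.0)
        assert (
            score_split_read(ev, stub_metrics(sc_tail=lo)).q
            >= score_split_read(ev, stub_metrics(sc_tail=hi)).q
        )


class TestReadPairScore:
    def test_mapq_zero(self):
        ev = _evidence(EvidenceKind.DISCORDANT_PAIR, mapq_a=0.0, mapq_b=60.0, ifs=900)
        assert score_read_pair(ev, stub_metrics(p_d=0.01, rp_tail=0.0)).q == pytest.approx(
            0.0, abs=1e-9
        )

    def test_full_fragment_tail(self):
        ev = _evidence(EvidenceKind.DISCORDANT_PAIR, mapq_a=100.0, mapq_b=100.0, ifs=300)
        q = score_read_pair(ev, stub_metrics(p_d=0.05, rp_tail=1.0)).q
        assert q == pytest.approx(0.0, abs=1e-6)

    def test_chimera_floor(self):
        ev = _evidence(EvidenceKind.DISCORDANT_PAIR, mapq_a=100.0, mapq_b=100.0, ifs=900)
        q = score_read_pair(ev, stub_metrics(p_d=0.01, rp_tail=0.0)).q
        assert q == pytest.approx(20.0, abs=1e-6)

    def test_oea_uses_p_u_and_no_fragment_term(self):
        ev = _evidence(EvidenceKind.ONE_END_ANCHOR, mapq_a=100.0)
        q = score_read_pair(ev, stub_metrics(p_u=0.001, p_d=0.5)).q
        assert q == pytest.approx(30.0, abs=1e-6)


class TestIndelScore:
    def test_mass_one(self):
        ev = _evidence(EvidenceKind.INDEL, mapq_a=60.0, indel_op="D", indel_len=5)
        assert score_indel_read(ev, stub_metrics(del_tail=1.0)).q == pytest.approx(0.0)

    def test_certain_mapping_small_mass(self):
        ev = _evidence(EvidenceKind.INDEL, mapq_a=100.0, indel_op="D", indel_len=50)
        q = score_indel_read(ev, stub_metrics(del_tail=0.001)).q
        assert q == pytest.approx(30.0, abs=1e-6)

    def test_mapq_zero(self):
        ev = _evidence(EvidenceKind.INDEL, mapq_a=0.0, indel_op="I", indel_len=5)
        assert score_indel_read(ev, stub_metrics(ins_tail=0.001)).q == pytest.approx(0.0)

    def test_uses_matching_operation_distribution(self):
        m = stub_metrics(ins_tail=0.1, del_tail=0.001)
        ins = _evidence(EvidenceKind.INDEL, mapq_a=100.0, indel_op="I", indel_len=5)
        dele = _evidence(EvidenceKind.INDEL, mapq_a=100.0, indel_op="D", indel_len=5)
        assert score_indel_read(ins, m).q == pytest.approx(10.0, abs=1e-6)
        assert score_indel_read(dele, m).q == pytest.approx(30.0, abs=1e-6)


class TestAssemblyScore:
    def test_all_mapq_zero(self):
        cons = [_evidence(EvidenceKind.SOFT_CLIP, mapq_a=0.0) for _ in range(3)]
        assert score_assembly(cons, 0.0, stub_metrics(sc_tail=0.01)).q == pytest.approx(0.0)

    def test_single_constituent_equals_promoted_score(self):
        m = stub_metrics(sc_tail=0.01)
        sc = _evidence(EvidenceKind.SOFT_CLIP, mapq_a=50.0)
        promoted = promote_constituent(sc)
        assert promoted.kind is EvidenceKind.SPLIT_READ
        promoted.mapq_b = 60.0
        expected = score_split_read(promoted, m).q
        assert score_assembly([sc], 60.0, m).q == pytest.approx(expected, abs=1e-9)

    def test_mixed_constituents_match_elementwise_max_oracle(self):
        m = stub_metrics(sc_tail=0.02, rp_tail=0.05, p_d=0.01, p_u=0.02)
        cons = [
            _evidence(EvidenceKind.SOFT_CLIP, mapq_a=40.0, l_sc=20),
            _evidence(EvidenceKind.SPLIT_READ, mapq_a=30.0, mapq_b=20.0, l_sc=30),
            _evidence(EvidenceKind.DISCORDANT_PAIR, mapq_a=50.0, mapq_b=50.0, ifs=800),
            _evidence(EvidenceKind.ONE_END_ANCHOR, mapq_a=35.0),
        ]
        realign_mapq = 42.0
        # independent oracle: promote each read, rescore with the assembly's
        # anchored/unanchored mapqs, take the max
        import copy

        anchored = max(c.mapq_a for c in cons)
        scores = []
        for c in cons:
            p = copy.copy(promote_constituent(c))
            p.mapq_a, p.mapq_b = anchored, realign_mapq
            if p.kind is EvidenceKind.SPLIT_READ:
                scores.append(score_split_read(p, m).q)
            elif p.ifs is None:
                from svbreakend.scoring import _combine, _pr_mapping

                scores.append(
                    _combine(_pr_mapping(p.mapq_a, p.mapq_b), m.p_u, 100.0).q
                )
            else:
                scores.append(score_read_pair(p, m).q)
        assert score_assembly(cons, realign_mapq, m).q == pytest.approx(
            max(scores), abs=1e-9
        )

    def test_empty_support_errors(self):
        with pytest.raises(ValueError):
            score_assembly([], 60.0, stub_metrics())
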