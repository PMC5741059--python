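"""Evidence-to-graph placement rules.

Each extracted read becomes one or more graph placements (see
:mod:`svbreakend.graph` for the placement semantics).  Reads supporting a
rearrangement *after* their anchor go to the forward graph of their
reference contig; reads supporting a rearrangement *before* it go to the
backward graph (built in reflected coordinates).  Placement identifiers are
per evidence piece (read id plus piece tag), so the read-partition property
of assembly holds piece-wise: a read clipped at both ends legitimately
contributes one piece to each graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._util import revcomp
from .evidence import EvidenceKind, ReadEvidence
from .graph import Placement, make_placement_bwd
from .metrics import LibraryMetrics

logger = logging.getLogger(__name__)


@dataclass
class PlacedEvidence:
    contig: str
    direction: str  # 'fwd' | 'bwd'
    placement: Placement


def piece_read_id(read_id: str, piece: str) -> str:
    return f"{read_id}|{piece}"


def base_read_id(piece_id: str) -> str:
    return piece_id.rsplit("|", 1)[0]


def _clip_placement(ev: ReadEvidence, side: str) -> PlacedEvidence | None:
    """Place a clipped read at the positions implied by full mapping,
    projected without gaps from the clip-side alignment boundary."""
    L = len(ev.seq)
    if L == 0:
        return None
    aq = ev.aligned_query_range
    if side == "R":
        # genome position of read base j: aln_ref_end - (last_aligned_idx - j)
        last_aligned = L - ev.right_clip - 1
        start = ev.aln_ref_end - last_aligned
        pl = Placement(
            read_id=piece_read_id(ev.read_id, "R"),
            seq=ev.seq,
            quals=list(ev.quals),
            mapq=ev.mapq_a,
            starts=[start],
            anchored_qrange=aq,
        )
        return PlacedEvidence(ev.locus_a.contig, "fwd", pl)
    # left clip: break before the anchor; backward graph via reflection
    start = ev.aln_ref_start - ev.left_clip
    pl = make_placement_bwd(
        piece_read_id(ev.read_id, "L"),
        ev.seq,
        ev.quals,
        ev.mapq_a,
        [start],
        anchored_qrange=aq,
    )
    return PlacedEvidence(ev.locus_a.contig, "bwd", pl)


def _indel_placements(ev: ReadEvidence) -> list[PlacedEvidence]:
    """An indel-containing read acts as two independent clipped reads."""
    out = []
    L = len(ev.seq)
    qpos = ev.indel_qpos
    if qpos is None:
        return out
    # forward piece: prefix aligned, everything past the op unanchored
    start_fwd = ev.locus_a.pos - (qpos - 1)
    out.append(
        PlacedEvidence(
            ev.locus_a.contig,
            "fwd",
            Placement(
                read_id=piece_read_id(ev.read_id, f"I{qpos}F"),
                seq=ev.seq,
                quals=list(ev.quals),
                mapq=ev.mapq_a,
                starts=[start_fwd],
                anchored_qrange=(ev.left_clip, qpos),
            ),
        )
    )
    qafter = qpos + (ev.indel_len if ev.indel_op == "I" else 0)
    last_aligned = L - ev.right_clip - 1
    start_bwd = ev.aln_ref_end - last_aligned
    out.append(
        PlacedEvidence(
            ev.locus_a.contig,
            "bwd",
            Placement(
                read_id=piece_read_id(ev.read_id, f"I{qpos}B"),
                seq=revcomp(ev.seq),
                quals=list(ev.quals)[::-1],
                mapq=ev.mapq_a,
                starts=[-(start_bwd + L - 1)],
                anchored_qrange=(ev.right_clip, L - qafter),
            ),
        )
    )
    return out


def _pair_partner_placement(
    ev: ReadEvidence, metrics: LibraryMetrics, seq: str, quals, read_id: str
) -> PlacedEvidence | None:
    """Place ``seq`` (the read whose position is dictated by the mate anchor)
    at every start position consistent with a concordant fragment."""
    if not metrics.pair_evidence_available:
        return None
    lo, hi = metrics.concordant_lo, metrics.concordant_hi
    L = len(seq)
    if L == 0:
        return None
    if ev.mate_strand == "+":
        # mate anchors a '+' break-end: the partner sits downstream on '-'
        m1 = ev.mate_start
        starts = list(range(m1 + lo - L, m1 + hi - L + 1))
        pl = Placement(read_id, seq, list(quals), ev.mapq_a, starts, None)
        return PlacedEvidence(ev.mate_contig, "fwd", pl)
    m2 = ev.mate_end
    starts = list(range(m2 - hi + 1, m2 - lo + 2))
    pl = make_placement_bwd(read_id, seq, quals, ev.mapq_a, starts, None)
    return PlacedEvidence(ev.mate_contig, "bwd", pl)


def _dp_placement(ev: ReadEvidence, metrics: LibraryMetrics) -> PlacedEvidence | None:
    # expected orientation opposite the mate; SAM seq is in this read's own
    # mapped orientation, so flip when it differs from the expected one
    expected = "-" if ev.mate_strand == "+" else "+"
    if ev.strand == expected:
        seq, quals = ev.seq, list(ev.quals)
    else:
        seq, quals = revcomp(ev.seq), list(ev.quals)[::-1]
    return _pair_partner_placement(
        ev, metrics, seq, quals, piece_read_id(ev.read_id, "P")
    )


def _oea_placements(ev: ReadEvidence, metrics: LibraryMetrics) -> list[PlacedEvidence]:
    """Anchored read at its own location plus the unmapped mate across the
    interval compatible with the anchor and fragment-size bounds."""
    out = []
    L = len(ev.seq)
    aq = ev.aligned_query_range
    if ev.strand == "+":
        start = ev.aln_ref_end - (L - ev.right_clip - 1)
        out.append(
            PlacedEvidence(
                ev.locus_a.contig,
                "fwd",
                Placement(
                    piece_read_id(ev.read_id, "A"), ev.seq, list(ev.quals),
                    ev.mapq_a, [start], aq,
                ),
            )
        )
    else:
        start = ev.aln_ref_start - ev.left_clip
        out.append(
            PlacedEvidence(
                ev.locus_a.contig,
                "bwd",
                make_placement_bwd(
                    piece_read_id(ev.read_id, "A"), ev.seq, ev.quals,
                    ev.mapq_a, [start], aq,
                ),
            )
        )
    if ev.mate_seq:
        # the unmapped mate, oriented opposite the anchor
        seq = ev.mate_seq
        quals = ev.mate_quals or [20] * len(seq)
        mate_id = base_read_id(ev.read_id)
        suffix = "/2" if ev.read_id.endswith("/1") else "/1"
        partner = _pair_partner_placement(
            ev, metrics, seq, quals, piece_read_id(mate_id + suffix, "U")
        )
        if partner is not None:
            out.append(partner)
    return out


def evidence_placements(
    ev: ReadEvidence, metrics: LibraryMetrics, k: int
) -> list[PlacedEvidence]:
    """All graph placements implied by one evidence record."""
    if len(ev.seq) < k and not (ev.mate_seq and len(ev.mate_seq) >= k):
        logger.debug("read %s shorter than k=%d; skipped", ev.read_id, k)
        return []
    if ev.kind in (EvidenceKind.SOFT_CLIP, EvidenceKind.SPLIT_READ):
        placed = _clip_placement(ev, ev.clip_side)
        return [placed] if placed else []
    if ev.kind is EvidenceKind.INDEL:
        return _indel_placements(ev)
    if ev.kind is EvidenceKind.DISCORDANT_PAIR:
        placed = _dp_placement(ev, metrics)
        return [placed] if placed else []
    if ev.kind is EvidenceKind.ONE_END_ANCHOR:
        return _oea_placements(ev, metrics)
    return []
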