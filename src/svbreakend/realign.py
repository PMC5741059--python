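"""Contig realignment: break-end contigs to breakpoint evidence.

Anchored contigs are locally realigned (Smith-Waterman) around the expected
contig position.  A contig that aligns to the reference full-length is
either indel-spanning evidence (its alignment contains an I/D) or a false
positive (gapless full alignment; discarded).  Otherwise the residue past
the anchored alignment is placed by the pluggable aligner; any residue the
placement itself leaves unaligned is realigned recursively (compound
realignment, depth-limited), yielding one piece of breakpoint evidence per
junction the contig spans.  Contigs with no anchored bases take the
breakpoint interval most consistent with their supporting read pairs.

This module also converts split-read and discordant-pair read evidence into
breakpoint evidence rectangles; split-read and assembly junction intervals
are widened by exact breakpoint microhomology, so evidence mapped to either
edge of a homologous junction coalesces into one clique.
"""

from __future__ import annotations

import logging

from ._util import revcomp
from .assembly import BreakendContig
from .breakpoints import BreakpointEvidence, SingleBreakend
from .evidence import EvidenceKind, ReadEvidence
from .homology import Junction, homology_intervals
from .metrics import LibraryMetrics
from .scoring import score_assembly, score_indel_read, score_read_pair, score_split_read
from .align import SWParams, smith_waterman

logger = logging.getLogger(__name__)

MIN_RESIDUE_LEN = 10
MAX_REALIGN_DEPTH = 4


def _junction_evidence(
    reference: dict,
    j: Junction,
    w: float,
    origin: str,
    category: str,
    read_ids,
    assembly_side: str | None = None,
    max_hom: int = 300,
) -> BreakpointEvidence:
    """Exact-junction evidence with intervals widened by microhomology."""
    low, high = homology_intervals(reference, j, max_hom)
    return BreakpointEvidence(
        contig_l=j.contig_l,
        s_l=low[0],
        e_l=low[1],
        d_l=j.dir_l,
        contig_h=j.contig_h,
        s_h=high[0],
        e_h=high[1],
        d_h=j.dir_h,
        w=w,
        origin=origin,
        category=category,
        read_ids=frozenset(read_ids),
        untemplated_seq=j.untemplated_seq,
        exact=True,
        nominal_l=j.pos_l,
        nominal_h=j.pos_h,
        assembly_side=assembly_side,
    )


def split_read_to_breakpoint(
    ev: ReadEvidence, reference: dict, metrics: LibraryMetrics
) -> BreakpointEvidence | None:
    """Breakpoint evidence from one split read."""
    if ev.kind is not EvidenceKind.SPLIT_READ or ev.locus_b is None:
        return None
    j = Junction(
        contig_l=ev.locus_a.contig,
        pos_l=ev.locus_a.pos,
        dir_l=ev.locus_a.direction,
        contig_h=ev.locus_b.contig,
        pos_h=ev.locus_b.pos,
        dir_h=ev.locus_b.direction,
        untemplated_seq=ev.untemplated_seq,
    )
    if ev.indel_op is not None:
        import copy

        as_indel = copy.copy(ev)
        as_indel.kind = EvidenceKind.INDEL
        w = score_indel_read(as_indel, metrics).q
    else:
        w = score_split_read(ev, metrics).q
    return _junction_evidence(
        reference, j, w, "SR", ev.category, {ev.read_id}
    )


def discordant_pair_to_breakpoint(
    ev: ReadEvidence, metrics: LibraryMetrics
) -> BreakpointEvidence | None:
    """Breakpoint rectangle from a discordant pair (its representative record).

    With this read aligned over [r1, r2] and the mate over [m1, m2] and
    concordant fragment sizes in [lo, hi], a '+' break-end may lie anywhere
    in [r2, r1 + hi - 1 - mate_len] and a '-' break-end anywhere in
    [r2 - hi + 1 + mate_len, r1] (bounding-rectangle approximation of the
    diagonal fragment-size constraint).
    """
    if ev.kind is not EvidenceKind.DISCORDANT_PAIR or not ev.pair_representative:
        return None
    if not metrics.pair_evidence_available or ev.mate_contig is None:
        return None
    hi = metrics.concordant_hi
    r1, r2 = ev.aln_ref_start, ev.aln_ref_end
    m1, m2 = ev.mate_start, ev.mate_end
    own_len = r2 - r1 + 1
    mate_len = m2 - m1 + 1
    d_a = "+" if ev.strand == "+" else "-"
    d_b = "+" if ev.mate_strand == "+" else "-"
    a_lo, a_hi = _pair_side(r1, r2, d_a, hi, mate_len)
    b_lo, b_hi = _pair_side(m1, m2, d_b, hi, own_len)
    w = score_read_pair(ev, metrics).q
    return BreakpointEvidence(
        contig_l=ev.locus_a.contig,
        s_l=a_lo,
        e_l=a_hi,
        d_l=d_a,
        contig_h=ev.mate_contig,
        s_h=b_lo,
        e_h=b_hi,
        d_h=d_b,
        w=w,
        origin="DP",
        category=ev.category,
        read_ids=frozenset({ev.read_id.rsplit("/", 1)[0] + "/pair"}),
    )


def _pair_side(start: int, end: int, direction: str, hi: int, other_len: int):
    """Break-end interval for one read of a pair (see caller docstring)."""
    if direction == "+":
        lo_i, hi_i = end, start + hi - 1 - other_len
    else:
        lo_i, hi_i = end - hi + 1 + other_len, start
    if hi_i < lo_i:
        point = end if direction == "+" else start
        return point, point
    return lo_i, hi_i


def evidence_to_breakpoints(
    evidence: list[ReadEvidence],
    reference: dict,
    metrics_by_library: dict[str, LibraryMetrics],
) -> list[BreakpointEvidence]:
    out = []
    for ev in evidence:
        metrics = metrics_by_library[ev.library_id]
        bp = None
        if ev.kind is EvidenceKind.SPLIT_READ:
            bp = split_read_to_breakpoint(ev, reference, metrics)
        elif ev.kind is EvidenceKind.DISCORDANT_PAIR:
            bp = discordant_pair_to_breakpoint(ev, metrics)
        if bp is not None:
            out.append(bp)
    return out


def realign_contig(
    contig: BreakendContig,
    reference: dict,
    aligner,
    metrics: LibraryMetrics,
    constituents: list[ReadEvidence],
    max_depth: int = MAX_REALIGN_DEPTH,
    min_mapq: float = 10.0,
    sw_params: SWParams = SWParams(),
    window_pad: int | None = None,
    dp_evidence: list[BreakpointEvidence] | None = None,
) -> tuple[list[BreakpointEvidence], list[SingleBreakend]]:
    """Realign one break-end contig; returns (breakpoints, single break-ends)."""
    if contig.anchor_pos is None:
        bp = _unanchored_breakpoint(contig, metrics, constituents, dp_evidence or [])
        return ([bp] if bp is not None else []), []
    refseq = str(reference[contig.contig])
    pad = window_pad
    if pad is None:
        pad = (metrics.concordant_hi or 600) + len(contig.seq_junction) + 50
    lo = max(0, contig.anchor_pos - pad)  # 0-based window start
    hi = min(len(refseq), contig.anchor_pos + pad)
    window = refseq[lo:hi]
    query = contig.seq_junction
    if contig.direction == "bwd":
        ctx = revcomp(window)
    else:
        ctx = window

    def ctx_to_genome(ctx_pos_1based: int) -> int:
        # ctx index i (1-based) -> genome position (1-based)
        if contig.direction == "fwd":
            return lo + ctx_pos_1based
        return hi - ctx_pos_1based + 1

    score = score_assembly(constituents, 60.0, metrics)
    breakpoints: list[BreakpointEvidence] = []
    singles: list[SingleBreakend] = []

    aln = smith_waterman(query, ctx, sw_params)
    if aln.score > 0 and aln.query_start == 0 and aln.query_end == len(query):
        # full-length alignment: indel-spanning or a false positive
        indels = _indel_junctions(contig, aln, ctx_to_genome)
        for j in indels:
            breakpoints.append(
                _junction_evidence(
                    reference, j, score.q, "ASSEMBLY", metrics.category,
                    contig.support, assembly_side="lo",
                )
            )
        return breakpoints, singles

    # place the break by realigning the anchored flank in a tight window
    # around the expected anchor (the whole-contig alignment can latch onto
    # the partner segment when the junction is nearby)
    apos = len(contig.anchored_seq)
    a_lo = max(0, contig.anchor_pos - apos - 50)
    a_hi = min(len(refseq), contig.anchor_pos + 50)
    a_window = refseq[a_lo:a_hi]
    a_ctx = a_window if contig.direction == "fwd" else revcomp(a_window)

    def a_ctx_to_genome(ctx_pos_1based: int) -> int:
        if contig.direction == "fwd":
            return a_lo + ctx_pos_1based
        return a_hi - ctx_pos_1based + 1

    a_aln = smith_waterman(contig.anchored_seq, a_ctx, sw_params)
    if a_aln.score <= 0:
        return [], []
    break_pos = a_ctx_to_genome(a_aln.ref_end)
    residue = query[a_aln.query_end :]
    if residue:
        _chase_residue(
            breakpoints,
            singles,
            reference,
            aligner,
            metrics,
            constituents,
            contig,
            from_contig=contig.contig,
            from_pos=break_pos,
            from_dir=contig.break_direction,
            residue=residue,
            depth=0,
            max_depth=max_depth,
            min_mapq=min_mapq,
        )
    return breakpoints, singles


def _chase_residue(
    breakpoints,
    singles,
    reference,
    aligner,
    metrics,
    constituents,
    contig,
    from_contig,
    from_pos,
    from_dir,
    residue,
    depth,
    max_depth,
    min_mapq,
):
    """Compound realignment: place the residue, emit a junction, recurse on
    whatever the placement leaves unaligned."""
    if depth >= max_depth or len(residue) < MIN_RESIDUE_LEN:
        if residue:
            singles.append(
                SingleBreakend(
                    contig=from_contig,
                    pos=from_pos,
                    direction=from_dir,
                    w=score_assembly(constituents, 0.0, metrics).q,
                    inserted_seq=residue,
                    read_ids=frozenset(contig.support),
                    category=metrics.category,
                )
            )
        return
    hit = aligner.align(residue)
    if hit is None or hit.mapq < min_mapq:
        singles.append(
            SingleBreakend(
                contig=from_contig,
                pos=from_pos,
                direction=from_dir,
                w=score_assembly(constituents, 0.0, metrics).q,
                inserted_seq=residue,
                read_ids=frozenset(contig.support),
                category=metrics.category,
            )
        )
        return
    if hit.strand == "+":
        partner = (hit.contig, hit.ref_start, "-")
        far = (hit.contig, hit.ref_end, "+")
    else:
        partner = (hit.contig, hit.ref_end, "+")
        far = (hit.contig, hit.ref_start, "-")
    j = Junction(
        contig_l=from_contig,
        pos_l=from_pos,
        dir_l=from_dir,
        contig_h=partner[0],
        pos_h=partner[1],
        dir_h=partner[2],
        untemplated_seq=residue[: hit.query_start],
    )
    score = score_assembly(constituents, hit.mapq, metrics)
    breakpoints.append(
        _junction_evidence(
            reference,
            j,
            score.q,
            "ASSEMBLY",
            metrics.category,
            contig.support,
            assembly_side="lo",  # anchored side; normalisation flips as needed
        )
    )
    tail = residue[hit.query_end :]
    if tail:
        _chase_residue(
            breakpoints,
            singles,
            reference,
            aligner,
            metrics,
            constituents,
            contig,
            from_contig=far[0],
            from_pos=far[1],
            from_dir=far[2],
            residue=tail,
            depth=depth + 1,
            max_depth=max_depth,
            min_mapq=min_mapq,
        )


def _indel_junctions(contig: BreakendContig, aln, ctx_to_genome) -> list[Junction]:
    out = []
    ref_pos = aln.ref_start  # 1-based position of next ctx base
    qpos = aln.query_start
    query = contig.seq_junction
    for op, length in aln.cigar:
        if op == "M":
            ref_pos += length
            qpos += length
        elif op == "D":
            before = ctx_to_genome(ref_pos)
            after = ctx_to_genome(ref_pos + length + 1)
            lo_p, hi_p = (before, after) if before < after else (after, before)
            out.append(
                Junction(
                    contig_l=contig.contig, pos_l=lo_p, dir_l="+",
                    contig_h=contig.contig, pos_h=hi_p, dir_h="-",
                )
            )
            ref_pos += length
        elif op == "I":
            before = ctx_to_genome(ref_pos)
            after = ctx_to_genome(ref_pos + 1)
            lo_p, hi_p = (before, after) if before < after else (after, before)
            ins = query[qpos : qpos + length]
            if contig.direction == "bwd":
                ins = revcomp(ins)
            out.append(
                Junction(
                    contig_l=contig.contig, pos_l=lo_p, dir_l="+",
                    contig_h=contig.contig, pos_h=hi_p, dir_h="-",
                    untemplated_seq=ins,
                )
            )
            qpos += length
    return out


def _unanchored_breakpoint(
    contig: BreakendContig,
    metrics: LibraryMetrics,
    constituents: list[ReadEvidence],
    dp_evidence: list[BreakpointEvidence],
) -> BreakpointEvidence | None:
    """Breakpoint interval most consistent with the contig's supporting pairs.

    The interval covered by the greatest number of supporting-pair rectangles
    is reported (widest interval on ties).
    """
    member = [
        bp
        for bp in dp_evidence
        if bp.read_ids & frozenset(r.rsplit("/", 1)[0] + "/pair" for r in contig.support)
    ]
    if not member:
        return None
    subset_counts: dict[tuple, int] = {}
    for bp in member:
        subset_counts[bp.subset] = subset_counts.get(bp.subset, 0) + 1
    subset = max(subset_counts, key=lambda s: (subset_counts[s], s))
    member = [bp for bp in member if bp.subset == subset]

    def best_interval(intervals):
        events = []
        for lo, hi in intervals:
            events.append((lo, 0))
            events.append((hi + 1, 1))
        events.sort()
        depth = best = 0
        cur_start = None
        best_iv = None
        for pos, kind in events:
            if kind == 0:
                depth += 1
                if depth > best or (depth == best and best_iv is None):
                    best = depth
                    cur_start = pos
            else:
                if depth == best and cur_start is not None:
                    iv = (cur_start, pos - 1)
                    if best_iv is None or (iv[1] - iv[0]) > (best_iv[1] - best_iv[0]):
                        best_iv = iv
                    cur_start = None
                depth -= 1
        return best_iv

    low = best_interval([(bp.s_l, bp.e_l) for bp in member])
    high = best_interval([(bp.s_h, bp.e_h) for bp in member])
    if low is None or high is None:
        return None
    score = score_assembly(constituents, 60.0, metrics)
    return BreakpointEvidence(
        contig_l=subset[0],
        s_l=low[0],
        e_l=low[1],
        d_l=subset[2],
        contig_h=subset[1],
        s_h=high[0],
        e_h=high[1],
        d_h=subset[3],
        w=score.q,
        origin="ASSEMBLY",
        category=metrics.category,
        read_ids=frozenset(contig.support),
        assembly_side="lo",
    )
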