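"""Extraction and classification of SV-supporting reads.

Reads supporting a structural variant are classified (non-exclusively) as:

* ``SOFT_CLIP`` — CIGAR contains a soft clip;
* ``INDEL`` — CIGAR contains an insertion or deletion operation;
* ``DISCORDANT_PAIR`` — both reads mapped, but the inferred fragment size
  falls outside the library's concordant bounds, the orientation is not
  forward-reverse inward-facing, or the reads map to different contigs;
* ``ONE_END_ANCHOR`` — exactly one read of the pair is mapped;
* ``SPLIT_READ`` — a soft clip whose clipped bases realign uniquely to the
  reference (or an indel-containing read, treated as a split read aligning
  to either side of the indel).

Pairs with both reads unmapped are not used. Reads flagged duplicate or
secondary/supplementary are dropped, as are soft clips shorter than 4 bp or
whose clipped bases average base quality < 5 (adapter/quality artifacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import pysam

from ._util import revcomp
from .metrics import LibraryMetrics, inferred_fragment_size

logger = logging.getLogger(__name__)

MIN_CLIP_LENGTH = 4
MIN_CLIP_MEAN_BASEQ = 5.0
#: MAPQ 255 means "unavailable" in SAM; the scoring model needs a finite value.
MAPQ_UNAVAILABLE_CEILING = 60


class EvidenceKind(str, Enum):
    SOFT_CLIP = "SC"
    SPLIT_READ = "SR"
    INDEL = "INDEL"
    DISCORDANT_PAIR = "DP"
    ONE_END_ANCHOR = "OEA"


@dataclass
class Locus:
    contig: str
    pos: int  # 1-based
    direction: str  # '+' retained sequence ends here; '-' retained sequence starts here

    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)


@dataclass
class ReadEvidence:
    kind: EvidenceKind
    read_id: str
    library_id: str
    category: str
    locus_a: Locus
    locus_b: Locus | None = None
    l_sc: int = 0
    ifs: int | None = None
    mapq_a: float = 0.0
    mapq_b: float | None = None
    seq: str = ""  # read bases, reference orientation of this read's own alignment
    quals: list[int] = field(default_factory=list)
    # alignment geometry (1-based closed reference interval of aligned bases)
    aln_ref_start: int = 0
    aln_ref_end: int = 0
    left_clip: int = 0
    right_clip: int = 0
    strand: str = "+"
    clip_side: str | None = None  # 'L' or 'R' for SOFT_CLIP / SPLIT_READ
    # mate geometry for pair evidence
    mate_contig: str | None = None
    mate_start: int | None = None
    mate_end: int | None = None
    mate_strand: str | None = None
    mate_seq: str | None = None  # unmapped mate bases (one-end anchors)
    mate_quals: list[int] | None = None
    pair_representative: bool = True  # lower-coordinate record of a DP pair
    # indel evidence
    indel_op: str | None = None  # 'I' or 'D'
    indel_len: int = 0
    indel_qpos: int | None = None  # query bases consumed before the op
    untemplated_seq: str = ""

    @property
    def clipped_seq(self) -> str:
        if self.clip_side == "L":
            return self.seq[: self.left_clip]
        if self.clip_side == "R":
            return self.seq[len(self.seq) - self.right_clip :]
        return ""

    @property
    def clipped_quals(self) -> list[int]:
        if self.clip_side == "L":
            return self.quals[: self.left_clip]
        if self.clip_side == "R":
            return self.quals[len(self.quals) - self.right_clip :]
        return []

    @property
    def aligned_query_range(self) -> tuple[int, int]:
        """Half-open read-offset range of aligned (non-clipped) bases."""
        return self.left_clip, len(self.seq) - self.right_clip


def effective_mapq(read: pysam.AlignedSegment) -> float:
    q = read.mapping_quality
    return float(MAPQ_UNAVAILABLE_CEILING if q == 255 else q)


def _pair_concordant_geometry(read: pysam.AlignedSegment) -> bool:
    """Forward-reverse inward-facing same-contig pair (seen from either read)."""
    if read.reference_id != read.next_reference_id:
        return False
    if read.is_reverse == read.mate_is_reverse:
        return False
    if read.is_reverse:
        return read.next_reference_start <= read.reference_start
    return read.reference_start <= read.next_reference_start


def pair_fragment_size(read: pysam.AlignedSegment) -> int | None:
    """Outermost-base span of the pair as seen from either mapped read."""
    if read.is_unmapped or read.mate_is_unmapped:
        return None
    if read.reference_id != read.next_reference_id:
        return None
    ifs = inferred_fragment_size(read)
    if ifs is not None:
        return ifs
    # rightmost / reverse read: mate (forward) starts at next_reference_start
    if read.is_reverse and not read.mate_is_reverse:
        if read.next_reference_start <= read.reference_start:
            return int(read.reference_end - read.next_reference_start)
    return None


def classify_read(
    read: pysam.AlignedSegment, metrics: LibraryMetrics
) -> set[EvidenceKind]:
    """Classify one alignment record; classes are not mutually exclusive.

    Pure: depends only on the record's fields and the library metrics.
    """
    kinds: set[EvidenceKind] = set()
    if read.is_duplicate or read.is_secondary or read.is_supplementary:
        return kinds
    if read.is_paired and read.is_unmapped and read.mate_is_unmapped:
        return kinds  # both-unmapped pairs carry no positional information
    if read.is_paired and (read.is_unmapped or read.mate_is_unmapped):
        kinds.add(EvidenceKind.ONE_END_ANCHOR)
    if read.is_unmapped:
        return kinds
    for op, length in read.cigartuples or []:
        if op == 4:
            kinds.add(EvidenceKind.SOFT_CLIP)
        elif op in (1, 2):
            kinds.add(EvidenceKind.INDEL)
    if read.is_paired and not read.is_unmapped and not read.mate_is_unmapped:
        if not _pair_concordant_geometry(read):
            kinds.add(EvidenceKind.DISCORDANT_PAIR)
        elif metrics.pair_evidence_available:
            ifs = pair_fragment_size(read)
            if ifs is not None and not (
                metrics.concordant_lo <= ifs <= metrics.concordant_hi
            ):
                kinds.add(EvidenceKind.DISCORDANT_PAIR)
    return kinds


def _read_suffix(read: pysam.AlignedSegment) -> str:
    if not read.is_paired:
        return ""
    return "/1" if read.is_read1 else "/2"


def _base_fields(read: pysam.AlignedSegment, metrics: LibraryMetrics) -> dict:
    cig = read.cigartuples or []
    left_clip = cig[0][1] if cig and cig[0][0] == 4 else 0
    right_clip = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    return dict(
        read_id=read.query_name + _read_suffix(read),
        library_id=metrics.library_id,
        category=metrics.category,
        mapq_a=effective_mapq(read),
        seq=read.query_sequence or "",
        quals=list(read.query_qualities or []),
        aln_ref_start=read.reference_start + 1,
        aln_ref_end=read.reference_end,  # pysam end is exclusive 0-based == inclusive 1-based
        left_clip=left_clip,
        right_clip=right_clip,
        strand="-" if read.is_reverse else "+",
    )


def _mate_fields(read: pysam.AlignedSegment) -> dict:
    mate_mapq = None
    try:
        mate_mapq = float(read.get_tag("MQ"))
    except KeyError:
        pass
    mate_span = None
    try:
        mc = read.get_tag("MC")
        mate_span = sum(
            int(n) for n, op in _split_cigar(mc) if op in "MDN=X"
        )
    except KeyError:
        mate_span = read.query_length or None
    mate_start = read.next_reference_start + 1
    return dict(
        mate_contig=read.header.get_reference_name(read.next_reference_id)
        if read.next_reference_id >= 0
        else None,
        mate_start=mate_start,
        mate_end=mate_start + (mate_span or 1) - 1,
        mate_strand="-" if read.mate_is_reverse else "+",
        mapq_b=mate_mapq,
    )


def _split_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def _soft_clip_records(read, metrics, base) -> list[ReadEvidence]:
    out = []
    contig = read.reference_name
    for side in ("L", "R"):
        clip = base["left_clip"] if side == "L" else base["right_clip"]
        if clip < MIN_CLIP_LENGTH:
            continue
        if side == "L":
            cq = base["quals"][:clip]
            locus = Locus(contig, base["aln_ref_start"], "-")
        else:
            cq = base["quals"][len(base["quals"]) - clip :]
            locus = Locus(contig, base["aln_ref_end"], "+")
        if cq and sum(cq) / len(cq) < MIN_CLIP_MEAN_BASEQ:
            continue
        out.append(
            ReadEvidence(
                kind=EvidenceKind.SOFT_CLIP,
                locus_a=locus,
                l_sc=clip,
                clip_side=side,
                **base,
            )
        )
    return out


def _indel_records(read, metrics, base) -> list[ReadEvidence]:
    out = []
    contig = read.reference_name
    ref_pos = read.reference_start  # 0-based; tracks last consumed ref base
    qpos = 0
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M,=,X
            ref_pos += length
            qpos += length
        elif op == 3:  # N
            ref_pos += length
        elif op in (4,):  # S
            qpos += length
        elif op in (1, 2):  # I / D
            out.append(
                ReadEvidence(
                    kind=EvidenceKind.INDEL,
                    locus_a=Locus(contig, ref_pos, "+"),  # last base before the op
                    indel_op="I" if op == 1 else "D",
                    indel_len=length,
                    indel_qpos=qpos,
                    l_sc=length,
                    untemplated_seq=base["seq"][qpos : qpos + length] if op == 1 else "",
                    **base,
                )
            )
            if op == 2:
                ref_pos += length
            else:
                qpos += length
    return out


def extract_evidence(
    alignment_files: list[str],
    metrics_per_file: list[LibraryMetrics],
    min_clip_length: int = MIN_CLIP_LENGTH,
) -> list[ReadEvidence]:
    """Extract SV-supporting evidence from coordinate-sorted alignment files.

    Returns the merged evidence list ordered by ``locus_a`` genome
    coordinate.  Discordant pairs yield one record per read (the
    lower-coordinate record is flagged ``pair_representative``); one-end
    anchors yield one record per pair, anchored at the mapped read and
    carrying the unmapped mate's bases.
    """
    streams = []
    for path, metrics in zip(alignment_files, metrics_per_file):
        streams.append(_extract_one(path, metrics, min_clip_length))
    merged: list[ReadEvidence] = [ev for stream in streams for ev in stream]
    merged.sort(key=lambda e: (e.locus_a.contig, e.locus_a.pos, e.read_id, e.kind.value))
    return merged


def _extract_one(path: str, metrics: LibraryMetrics, min_clip_length: int):
    out: list[ReadEvidence] = []
    oea_pending: dict[str, pysam.AlignedSegment] = {}
    last_key: tuple[int, int] | None = None
    with pysam.AlignmentFile(path, require_index=False) as fh:
        for read in fh:
            if not read.is_unmapped:
                key = (read.reference_id, read.reference_start)
                if last_key is not None and key < last_key:
                    raise ValueError(
                        f"{path}: not coordinate-sorted at record {read.query_name}"
                    )
                last_key = key
            kinds = classify_read(read, metrics)
            if not kinds:
                continue
            if EvidenceKind.ONE_END_ANCHOR in kinds:
                mate = oea_pending.pop(read.query_name, None)
                if mate is None:
                    oea_pending[read.query_name] = read
                else:
                    mapped, unmapped = (read, mate) if mate.is_unmapped else (mate, read)
                    if mapped.is_unmapped:
                        mapped, unmapped = unmapped, mapped
                    ev = _oea_record(mapped, unmapped, metrics)
                    if ev is not None:
                        out.append(ev)
            if read.is_unmapped:
                continue
            base = _base_fields(read, metrics)
            if EvidenceKind.SOFT_CLIP in kinds:
                out.extend(_soft_clip_records(read, metrics, base))
            if EvidenceKind.INDEL in kinds:
                out.extend(_indel_records(read, metrics, base))
            if EvidenceKind.DISCORDANT_PAIR in kinds:
                ev = _dp_record(read, metrics, base)
                if ev is not None:
                    out.append(ev)
    # OEA pairs whose unmapped record was absent from the file: anchor-only
    for read in oea_pending.values():
        if not read.is_unmapped:
            ev = _oea_record(read, None, metrics)
            if ev is not None:
                out.append(ev)
    return out


def _dp_record(read, metrics: LibraryMetrics, base) -> ReadEvidence | None:
    if not metrics.pair_evidence_available:
        return None
    contig = read.reference_name
    mate = _mate_fields(read)
    if mate["mapq_b"] is None:
        mate["mapq_b"] = base["mapq_a"]
    ifs = pair_fragment_size(read)
    # break-end opens away from the mate: a forward read anchors a '+'
    # break-end after its last aligned base, a reverse read a '-' before its first
    if base["strand"] == "+":
        locus_a = Locus(contig, base["aln_ref_end"], "+")
    else:
        locus_a = Locus(contig, base["aln_ref_start"], "-")
    self_key = (contig, base["aln_ref_start"], base["read_id"])
    mate_key = (mate["mate_contig"], mate["mate_start"], "")
    representative = (self_key[:2], read.is_read1) <= (mate_key[:2], not read.is_read1)
    kwargs = dict(base)
    kwargs.update(mate)
    return ReadEvidence(
        kind=EvidenceKind.DISCORDANT_PAIR,
        locus_a=locus_a,
        ifs=ifs,
        pair_representative=(self_key[:2] < mate_key[:2])
        or (self_key[:2] == mate_key[:2] and read.is_read1),
        **kwargs,
    )


def _oea_record(mapped, unmapped, metrics: LibraryMetrics) -> ReadEvidence | None:
    base = _base_fields(mapped, metrics)
    contig = mapped.reference_name
    if base["strand"] == "+":
        locus_a = Locus(contig, base["aln_ref_end"], "+")
    else:
        locus_a = Locus(contig, base["aln_ref_start"], "-")
    return ReadEvidence(
        kind=EvidenceKind.ONE_END_ANCHOR,
        locus_a=locus_a,
        mate_seq=(unmapped.query_sequence or "") if unmapped is not None else None,
        mate_quals=list(unmapped.query_qualities or []) if unmapped is not None else None,
        mate_contig=contig,
        mate_start=base["aln_ref_start"],
        mate_end=base["aln_ref_end"],
        mate_strand=base["strand"],
        **base,
    )


def identify_split_reads(
    evidence: list[ReadEvidence],
    aligner,
    min_mapq: float = 10.0,
) -> list[ReadEvidence]:
    """Promote soft clips whose clipped bases realign uniquely to split reads.

    ``aligner`` maps a query sequence to its best reference hit (or None);
    see :class:`svbreakend.align.SeedAligner` for the default contract.
    Indel-containing reads are emitted as split reads spanning the indel.
    Aligner failures leave the record a soft clip with a logged warning.
    """
    out: list[ReadEvidence] = []
    for ev in evidence:
        if ev.kind is EvidenceKind.INDEL:
            out.append(ev)
            out.append(_indel_split_read(ev))
            continue
        if ev.kind is not EvidenceKind.SOFT_CLIP:
            out.append(ev)
            continue
        outgoing = ev.clipped_seq if ev.locus_a.direction == "+" else revcomp(ev.clipped_seq)
        try:
            hit = aligner.align(outgoing)
        except Exception:  # pragma: no cover - defensive
            logger.warning("realignment failed for %s; kept as soft clip", ev.read_id)
            out.append(ev)
            continue
        if hit is None or hit.mapq < min_mapq:
            out.append(ev)
            continue
        sr = _clip_to_split_read(ev, outgoing, hit)
        out.append(sr)
    out.sort(key=lambda e: (e.locus_a.contig, e.locus_a.pos, e.read_id, e.kind.value))
    return out


def _clip_to_split_read(ev: ReadEvidence, outgoing: str, hit) -> ReadEvidence:
    import copy

    sr = copy.copy(ev)
    sr.kind = EvidenceKind.SPLIT_READ
    if hit.strand == "+":
        sr.locus_b = Locus(hit.contig, hit.ref_start, "-")
    else:
        sr.locus_b = Locus(hit.contig, hit.ref_end, "+")
    sr.mapq_b = float(hit.mapq)
    sr.untemplated_seq = outgoing[: hit.query_start]
    return sr


def _indel_split_read(ev: ReadEvidence) -> ReadEvidence:
    import copy

    sr = copy.copy(ev)
    sr.kind = EvidenceKind.SPLIT_READ
    contig = ev.locus_a.contig
    before = ev.locus_a.pos
    if ev.indel_op == "D":
        after = before + ev.indel_len + 1
        sr.untemplated_seq = ""
    else:
        after = before + 1
        sr.untemplated_seq = ev.untemplated_seq  # the inserted bases
    sr.locus_a = Locus(contig, before, "+")
    sr.locus_b = Locus(contig, after, "-")
    sr.mapq_b = ev.mapq_a
    return sr
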