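"""Synthetic data: references, planted structural variants, simulated reads.

Everything the pipeline consumes can be generated deterministically from a
seed, so the whole caller is testable without downloads:

* :func:`generate_genome` — random reference sequence at a target GC;
* :func:`plant_svs` — apply non-overlapping DEL/INS/INV/DUP/TRA events to a
  reference, returning the mutated haplotype together with truth records
  (junctions, sizes, homology) and a haplotype-to-reference segment map;
* :func:`simulate_reads` — paired-end reads with normal fragment sizes and
  uniform per-base error, written as a coordinate-sorted SAM whose
  alignments are derived from the truth segment map: a read crossing a
  planted junction is emitted soft-clipped at the reference position a
  correct aligner would choose, reads inside novel insertions are emitted
  unmapped with a mapped mate, and base qualities are the Phred equivalent
  of the error rate with +/-5 jitter.

Default simulation conditions are 2x100 bp reads, fragment size 300 +/- 30,
1% base error — typical short-read whole-genome parameters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._util import revcomp
from .homology import Junction, exact_homology, homology_intervals

_BASES = np.array(list("ACGT"))


def generate_genome(
    length: int, gc: float = 0.5, seed: int = 0, name: str = "chr1"
) -> dict[str, str]:
    """Random reference sequence with the given GC content."""
    if length < 1000:
        raise ValueError("genome length must be at least 1 kb")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=probs)
    return {name: "".join(seq)}


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    fai = path + ".fai"
    if os.path.exists(fai):
        os.unlink(fai)


@dataclass
class SVSpec:
    """One event to plant.  ``pos`` is 1-based; DEL/INV/DUP affect
    ``[pos, pos+size-1]``; INS inserts ``ins_seq`` after ``pos``; TRA joins
    ``contig[..pos]`` to ``contig2[pos2..]`` (unbalanced, one junction)."""

    kind: str  # DEL | INS | INV | DUP | TRA
    contig: str
    pos: int
    size: int = 0
    ins_seq: str = ""
    contig2: str | None = None
    pos2: int | None = None


@dataclass
class Segment:
    """Mapping of haplotype bases back to the reference (1-based closed)."""

    hap_start: int
    hap_end: int
    ref_contig: str | None  # None for novel (inserted) sequence
    ref_start: int = 0
    strand: str = "+"

    def ref_pos(self, hap_pos: int) -> int:
        off = hap_pos - self.hap_start
        if self.strand == "+":
            return self.ref_start + off
        return self.ref_start + (self.hap_end - self.hap_start) - off


@dataclass
class TruthRecord:
    kind: str
    junction: Junction
    size: int = 0
    homology_len: int = 0
    homology_low: tuple[int, int] = (0, 0)
    homology_high: tuple[int, int] = (0, 0)
    untemplated_seq: str = ""
    zygosity: str = "het"


@dataclass
class Haplotype:
    contigs: dict[str, str]
    segments: dict[str, list[Segment]]


def reference_haplotype(genome: dict[str, str]) -> Haplotype:
    segs = {
        name: [Segment(1, len(seq), name, 1, "+")] for name, seq in genome.items()
    }
    return Haplotype(contigs=dict(genome), segments=segs)


def _truth(genome, kind, junction, size=0, untemplated="") -> TruthRecord:
    left, right, _ = exact_homology(genome, junction)
    low, high = homology_intervals(genome, junction)
    return TruthRecord(
        kind=kind,
        junction=junction,
        size=size,
        homology_len=left + right,
        homology_low=low,
        homology_high=high,
        untemplated_seq=untemplated,
    )


def plant_svs(
    genome: dict[str, str], events: list[SVSpec], seed: int = 0
) -> tuple[Haplotype, list[TruthRecord]]:
    """Apply events to a reference; returns the mutated haplotype and truth.

    Events on the same contig must not overlap.  TRA events consume the
    suffix of ``contig`` and of ``contig2``; at most one TRA per contig pair
    and it must not overlap other events.
    """
    by_contig: dict[str, list[SVSpec]] = {}
    tra: SVSpec | None = None
    for ev in events:
        if ev.kind == "TRA":
            if tra is not None:
                raise ValueError("only one translocation supported per call")
            tra = ev
        else:
            by_contig.setdefault(ev.contig, []).append(ev)
    for contig, evs in by_contig.items():
        evs.sort(key=lambda e: e.pos)
        last_end = 0
        for ev in evs:
            span = ev.size if ev.kind in ("DEL", "INV", "DUP") else 0
            if ev.pos <= last_end:
                raise ValueError(f"overlapping events on {contig} at {ev.pos}")
            last_end = ev.pos + max(span, 1) - 1
    if tra is not None:
        for ev in by_contig.get(tra.contig, []):
            if ev.pos + ev.size > tra.pos:
                raise ValueError("event overlaps the translocated suffix")
        for ev in by_contig.get(tra.contig2, []):
            if ev.pos + ev.size >= tra.pos2:
                raise ValueError("event overlaps the translocated suffix")
    truth: list[TruthRecord] = []
    contigs: dict[str, str] = {}
    segments: dict[str, list[Segment]] = {}
    for name, refseq in genome.items():
        evs = by_contig.get(name, [])
        pieces: list[tuple[str, Segment | None]] = []
        cursor = 1  # next unconsumed reference base

        def take(upto: int):
            nonlocal cursor
            if upto >= cursor:
                pieces.append(
                    (refseq[cursor - 1 : upto], Segment(0, 0, name, cursor, "+"))
                )
                cursor = upto + 1

        for ev in evs:
            if ev.kind == "DEL":
                take(ev.pos - 1)
                cursor = ev.pos + ev.size
                truth.append(
                    _truth(
                        genome,
                        "DEL",
                        Junction(name, ev.pos - 1, "+", name, ev.pos + ev.size, "-"),
                        size=ev.size,
                    )
                )
            elif ev.kind == "INS":
                take(ev.pos)
                pieces.append((ev.ins_seq, None))
                truth.append(
                    _truth(
                        genome,
                        "INS",
                        Junction(
                            name, ev.pos, "+", name, ev.pos + 1, "-",
                            untemplated_seq=ev.ins_seq,
                        ),
                        size=len(ev.ins_seq),
                        untemplated=ev.ins_seq,
                    )
                )
            elif ev.kind == "INV":
                take(ev.pos - 1)
                inv = revcomp(refseq[ev.pos - 1 : ev.pos + ev.size - 1])
                pieces.append((inv, Segment(0, 0, name, ev.pos, "-")))
                cursor = ev.pos + ev.size
                truth.append(
                    _truth(
                        genome,
                        "INV",
                        Junction(name, ev.pos - 1, "+", name, ev.pos + ev.size - 1, "+"),
                        size=ev.size,
                    )
                )
                truth.append(
                    _truth(
                        genome,
                        "INV",
                        Junction(name, ev.pos, "-", name, ev.pos + ev.size, "-"),
                        size=ev.size,
                    )
                )
            elif ev.kind == "DUP":
                take(ev.pos + ev.size - 1)
                dup = refseq[ev.pos - 1 : ev.pos + ev.size - 1]
                pieces.append((dup, Segment(0, 0, name, ev.pos, "+")))
                truth.append(
                    _truth(
                        genome,
                        "DUP",
                        Junction(name, ev.pos, "-", name, ev.pos + ev.size - 1, "+"),
                        size=ev.size,
                    )
                )
            else:
                raise ValueError(f"unknown event kind {ev.kind}")
        if tra is not None and tra.contig == name:
            take(tra.pos)
            other = genome[tra.contig2]
            pieces.append(
                (other[tra.pos2 - 1 :], Segment(0, 0, tra.contig2, tra.pos2, "+"))
            )
            cursor = len(refseq) + 1  # suffix of this contig is lost
            truth.append(
                _truth(
                    genome,
                    "TRA",
                    Junction(name, tra.pos, "+", tra.contig2, tra.pos2, "-"),
                )
            )
        elif tra is not None and tra.contig2 == name:
            # the suffix from pos2 moved to the derivative of tra.contig
            take(tra.pos2 - 1)
            cursor = len(refseq) + 1
        take(len(refseq))
        # assemble the haplotype contig and its segment map
        seq_parts: list[str] = []
        segs: list[Segment] = []
        hap_pos = 1
        for text, seg in pieces:
            if not text:
                continue
            seq_parts.append(text)
            end = hap_pos + len(text) - 1
            if seg is None:
                segs.append(Segment(hap_pos, end, None))
            else:
                segs.append(
                    Segment(hap_pos, end, seg.ref_contig, seg.ref_start, seg.strand)
                )
            hap_pos = end + 1
        contigs[name] = "".join(seq_parts)
        segments[name] = _merge_colinear(segs)
    return Haplotype(contigs=contigs, segments=segments), truth


def _merge_colinear(segs: list[Segment]) -> list[Segment]:
    """Merge haplotype-adjacent, reference-colinear segments (e.g. the second
    copy of a tandem duplication flowing into the downstream sequence): an
    aligner would map reads across such boundaries contiguously."""
    out: list[Segment] = []
    for seg in segs:
        if out:
            prev = out[-1]
            if (
                prev.ref_contig is not None
                and seg.ref_contig == prev.ref_contig
                and prev.strand == seg.strand == "+"
                and seg.hap_start == prev.hap_end + 1
                and seg.ref_start == prev.ref_start + (prev.hap_end - prev.hap_start) + 1
            ):
                out[-1] = Segment(
                    prev.hap_start, seg.hap_end, prev.ref_contig, prev.ref_start, "+"
                )
                continue
        out.append(seg)
    return out


def _qualities(rng, n: int, error_rate: float) -> np.ndarray:
    q = int(round(-10 * np.log10(max(error_rate, 1e-6))))
    return np.clip(rng.integers(q - 5, q + 6, size=n), 2, 60).astype(np.int64)


def _mutate(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _align_to_reference(hap: Haplotype, contig: str, s: int, e: int):
    """Best truth alignment of haplotype interval [s, e]: the overlapping
    reference-mapped segment with the largest overlap (ties to the first)."""
    best = None
    for seg in hap.segments.get(contig, []):
        if seg.ref_contig is None:
            continue
        lo, hi = max(s, seg.hap_start), min(e, seg.hap_end)
        if hi < lo:
            continue
        ov = hi - lo + 1
        if best is None or ov > best[0]:
            best = (ov, seg, lo, hi)
    return best


def simulate_reads(
    haplotypes: list[Haplotype],
    reference: dict[str, str],
    sam_path: str,
    coverage: float = 60.0,
    read_len: int = 100,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    error_rate: float = 0.01,
    seed: int = 0,
    fastq_prefix: str | None = None,
    library_id: str = "simlib",
) -> int:
    """Simulate paired-end reads and write a coordinate-sorted SAM.

    Total coverage is split evenly across haplotypes.  Returns the number of
    pairs written.  If ``fastq_prefix`` is given, ``<prefix>_1.fastq`` and
    ``<prefix>_2.fastq`` are written as well.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_mean < read_len:
        raise ValueError("fragment mean must be at least the read length")
    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in reference.items()
            ],
            "RG": [{"ID": library_id, "SM": "sim"}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    fq1 = fq2 = None
    if fastq_prefix:
        fq1 = open(fastq_prefix + "_1.fastq", "w")
        fq2 = open(fastq_prefix + "_2.fastq", "w")
    n_pairs = 0
    cov_each = coverage / max(len(haplotypes), 1)
    for h, hap in enumerate(haplotypes):
        for contig, seq in sorted(hap.contigs.items()):
            L = len(seq)
            if L < frag_mean:
                continue
            pairs = int(round(cov_each * L / (2 * read_len)))
            for p in range(pairs):
                frag = int(round(rng.normal(frag_mean, frag_sd)))
                frag = max(frag, read_len)
                if frag > L:
                    continue
                f1 = int(rng.integers(1, L - frag + 2))
                f2 = f1 + frag - 1
                name = f"sim{h}.{contig}.{n_pairs}"
                r1_hap = seq[f1 - 1 : f1 - 1 + read_len]
                r2_hap = seq[f2 - read_len : f2]
                r1 = _mutate(rng, r1_hap, error_rate)
                r2 = _mutate(rng, revcomp(r2_hap), error_rate)
                q1 = _qualities(rng, read_len, error_rate)
                q2 = _qualities(rng, read_len, error_rate)
                a1 = _align_to_reference(hap, contig, f1, f1 + read_len - 1)
                a2 = _align_to_reference(hap, contig, f2 - read_len + 1, f2)
                recs = _pair_records(
                    header, name, r1, q1, a1, f1, r2, q2, a2, f2 - read_len + 1,
                    read_len, library_id,
                )
                if recs:
                    records.extend(recs)
                    n_pairs += 1
                    if fq1:
                        fq1.write(f"@{name}/1\n{r1}\n+\n{_qstr(q1)}\n")
                        fq2.write(f"@{name}/2\n{r2}\n+\n{_qstr(q2)}\n")
    if fq1:
        fq1.close()
        fq2.close()
    records.sort(
        key=lambda r: (
            r.reference_id if r.reference_id >= 0 else 10**6,
            r.reference_start,
            r.query_name,
        )
    )
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for rec in records:
            out.write(rec)
    return n_pairs


def _qstr(quals) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def _cigar_for(aln, s: int, read_len: int):
    """(cigar string, ref_start0, reverse_flag_flip) for a truth alignment of
    the hap-forward interval starting at s."""
    ov, seg, lo, hi = aln
    pre = lo - s  # hap-forward bases before the aligned block
    post = read_len - pre - ov
    if seg.strand == "+":
        ref_start = seg.ref_pos(lo)
        cig = []
        if pre:
            cig.append((4, pre))
        cig.append((0, ov))
        if post:
            cig.append((4, post))
        return cig, ref_start - 1, False
    ref_start = seg.ref_pos(hi)
    cig = []
    if post:
        cig.append((4, post))
    cig.append((0, ov))
    if pre:
        cig.append((4, pre))
    return cig, ref_start - 1, True


def _pair_records(
    header, name, r1, q1, a1, s1, r2, q2, a2, s2, read_len, library_id
):
    if a1 is None and a2 is None:
        return []
    recs = []
    for idx, (r, q, a, s, mate_a, mate_s) in enumerate(
        ((r1, q1, a1, s1, a2, s2), (r2, q2, a2, s2, a1, s1))
    ):
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.is_paired = True
        rec.is_read1 = idx == 0
        rec.is_read2 = idx == 1
        # reads are sequenced hap-forward (R1) and hap-reverse (R2); SAM
        # stores ref-forward bases
        sequenced_fwd = idx == 0
        if a is None:
            rec.is_unmapped = True
            rec.query_sequence = r
            rec.query_qualities = pysam.qualitystring_to_array(_qstr(q))
        else:
            cig, ref_start0, flip = _cigar_for(a, s, read_len)
            reverse = (not sequenced_fwd) ^ flip
            rec.is_reverse = reverse
            # SAM sequence: reference-forward orientation
            hap_fwd = r if sequenced_fwd else revcomp(r)
            hap_fwd_q = list(q) if sequenced_fwd else list(q)[::-1]
            if flip:
                sam_seq = revcomp(hap_fwd)
                sam_q = hap_fwd_q[::-1]
            else:
                sam_seq = hap_fwd
                sam_q = hap_fwd_q
            rec.query_sequence = sam_seq
            rec.query_qualities = pysam.qualitystring_to_array(_qstr(sam_q))
            rec.reference_id = header.get_tid(a[1].ref_contig)
            rec.reference_start = ref_start0
            rec.cigartuples = cig
            rec.mapping_quality = 60
        recs.append(rec)
    r1_rec, r2_rec = recs
    for rec, other in ((r1_rec, r2_rec), (r2_rec, r1_rec)):
        if other.is_unmapped:
            rec.mate_is_unmapped = True
            other.reference_id = rec.reference_id
            other.reference_start = rec.reference_start
        else:
            rec.mate_is_unmapped = False
            rec.next_reference_id = other.reference_id
            rec.next_reference_start = other.reference_start
            rec.mate_is_reverse = other.is_reverse
            rec.set_tag("MC", other.cigarstring)
            rec.set_tag("MQ", other.mapping_quality)
    # mates of unmapped reads still need next fields
    for rec, other in ((r1_rec, r2_rec), (r2_rec, r1_rec)):
        if rec.is_unmapped:
            rec.next_reference_id = other.reference_id
            rec.next_reference_start = other.reference_start
            rec.mate_is_reverse = other.is_reverse
        if rec.next_reference_id is None or rec.next_reference_id < 0:
            rec.next_reference_id = rec.reference_id
            rec.next_reference_start = rec.reference_start
    rec1, rec2 = recs
    if not rec1.is_unmapped and not rec2.is_unmapped:
        tlen = 0
        if rec1.reference_id == rec2.reference_id:
            lo = min(rec1.reference_start, rec2.reference_start)
            hi = max(rec1.reference_end, rec2.reference_end)
            tlen = hi - lo
            rec1.template_length = tlen if rec1.reference_start <= rec2.reference_start else -tlen
            rec2.template_length = -rec1.template_length
    for rec in recs:
        rec.set_tag("RG", library_id)
    return recs


def write_truth_bedpe(truth: list[TruthRecord], path: str) -> None:
    """Truth junctions as BEDPE (0-based half-open intervals per break-end)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\thomlen\tuntemplated\n"
        )
        for i, t in enumerate(truth):
            j = t.junction
            fh.write(
                f"{j.contig_l}\t{j.pos_l - 1}\t{j.pos_l}\t"
                f"{j.contig_h}\t{j.pos_h - 1}\t{j.pos_h}\t"
                f"{t.kind}_{i}\t.\t{j.dir_l}\t{j.dir_h}\t"
                f"{t.homology_len}\t{t.untemplated_seq or '.'}\n"
            )
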