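"""VCFv4.2 break-end (BND) output.

Each breakpoint is written as a pair of BND records linked by MATEID, with
untemplated inserted sequence embedded in the bracket ALT allele, standard
CIPOS/HOMLEN/HOMSEQ homology fields, the nonstandard IHOMPOS inexact
homology interval, per-origin and per-category support breakdowns, and a
FILTER of PASS (high confidence) or LOW_QUAL.  Break-ends without a located
partner are written with the unpaired break-end ALT notation.
"""

from __future__ import annotations

import pysam

from ._util import revcomp
from .breakpoints import SingleBreakend
from .calling import VariantCall

_HEADER_INFO = [
    ('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'),
    ('##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">'),
    ('##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">'),
    ('##INFO=<ID=HOMLEN,Number=.,Type=Integer,Description="Length of breakpoint microhomology">'),
    ('##INFO=<ID=HOMSEQ,Number=.,Type=String,Description="Breakpoint microhomology sequence">'),
    ('##INFO=<ID=IHOMPOS,Number=2,Type=Integer,Description="Interval of inexact homology around the break-end">'),
    ('##INFO=<ID=SVINS,Number=.,Type=String,Description="Untemplated inserted sequence at the junction">'),
    ('##INFO=<ID=SR_COUNT,Number=1,Type=Integer,Description="Split reads assigned to this variant">'),
    ('##INFO=<ID=DP_COUNT,Number=1,Type=Integer,Description="Discordant pairs assigned to this variant">'),
    ('##INFO=<ID=AS_COUNT,Number=1,Type=Integer,Description="Assemblies assigned to this variant">'),
    ('##INFO=<ID=SR_QUAL,Number=1,Type=Float,Description="Summed split read score">'),
    ('##INFO=<ID=DP_QUAL,Number=1,Type=Float,Description="Summed discordant pair score">'),
    ('##INFO=<ID=AS_QUAL,Number=1,Type=Float,Description="Summed assembly score">'),
    ('##INFO=<ID=ASSEMBLY_SIDES,Number=1,Type=Integer,Description="Break-ends with assembly support (0/1/2)">'),
    ('##INFO=<ID=CAT_SUPPORT,Number=.,Type=String,Description="Per-category support as category|count|qual">'),
    ('##INFO=<ID=CONFIDENCE,Number=1,Type=String,Description="Call confidence (HIGH/LOW)">'),
    ('##FILTER=<ID=LOW_QUAL,Description="Low-confidence call, retained for high-sensitivity analyses">'),
]


def _alt(ref_base: str, ins: str, partner_contig: str, partner_pos: int,
         partner_dir: str, direction: str) -> str:
    bracket = (
        f"[{partner_contig}:{partner_pos}[" if partner_dir == "-"
        else f"]{partner_contig}:{partner_pos}]"
    )
    if direction == "+":
        return f"{ref_base}{ins}{bracket}"
    return f"{bracket}{ins}{ref_base}"


def _info_common(call: VariantCall) -> dict:
    info = {"SVTYPE": "BND"}
    sup = call.support_breakdown
    for origin, (ck, qk) in (
        ("SR", ("SR_COUNT", "SR_QUAL")),
        ("DP", ("DP_COUNT", "DP_QUAL")),
        ("ASSEMBLY", ("AS_COUNT", "AS_QUAL")),
    ):
        entry = sup.get(origin)
        info[ck] = entry["count"] if entry else 0
        info[qk] = round(entry["qual"], 2) if entry else 0.0
    info["ASSEMBLY_SIDES"] = call.assembly_sides
    info["CONFIDENCE"] = call.confidence
    cats = [
        f"{cat}|{v['count']}|{round(v['qual'], 2)}"
        for cat, v in sorted(call.category_breakdown.items())
    ]
    if cats:
        info["CAT_SUPPORT"] = ",".join(cats)
    if call.exact:
        info["HOMLEN"] = call.homlen
        if call.homseq:
            info["HOMSEQ"] = call.homseq
        if call.ihompos is not None:
            info["IHOMPOS"] = call.ihompos
    if call.untemplated_seq:
        info["SVINS"] = call.untemplated_seq
    return info


def write_vcf(
    calls: list[VariantCall],
    singles: list[SingleBreakend],
    reference: dict,
    path: str,
) -> None:
    header = pysam.VariantHeader()
    header.add_line("##source=svbreakend")
    for line in _HEADER_INFO:
        header.add_line(line)
    for name, seq in reference.items():
        header.contigs.add(name, length=len(seq))
    with pysam.VariantFile(path, "w", header=header) as out:
        n = 0
        for call in sorted(calls, key=lambda c: c.key):
            n += 1
            base = f"bnd{n}"
            ref_l = str(reference[call.contig_l])[call.pos_l - 1].upper()
            ref_h = str(reference[call.contig_h])[call.pos_h - 1].upper()
            ins_lo = call.untemplated_seq if call.d_l == "+" else revcomp(call.untemplated_seq)
            ins_hi = call.untemplated_seq if call.d_h == "-" else revcomp(call.untemplated_seq)
            for tag, contig, pos, direction, refb, ins, p_contig, p_pos, p_dir, cipos in (
                ("o", call.contig_l, call.pos_l, call.d_l, ref_l, ins_lo,
                 call.contig_h, call.pos_h, call.d_h, call.cipos_l),
                ("h", call.contig_h, call.pos_h, call.d_h, ref_h, ins_hi,
                 call.contig_l, call.pos_l, call.d_l, call.cipos_h),
            ):
                rec = out.new_record(
                    contig=contig,
                    start=pos - 1,
                    alleles=(refb, _alt(refb, ins, p_contig, p_pos, p_dir, direction)),
                    id=f"{base}{tag}",
                )
                rec.qual = round(call.qual, 2)
                rec.filter.add("PASS" if call.confidence == "HIGH" else "LOW_QUAL")
                info = _info_common(call)
                info["MATEID"] = f"{base}{'h' if tag == 'o' else 'o'}"
                info["CIPOS"] = cipos
                for key, val in info.items():
                    rec.info[key] = val
                out.write(rec)
        for sb in sorted(singles, key=lambda s: (s.contig, s.pos)):
            n += 1
            refb = str(reference[sb.contig])[sb.pos - 1].upper()
            alt = (
                f"{refb}{sb.inserted_seq}."
                if sb.direction == "+"
                else f".{sb.inserted_seq}{refb}"
            )
            rec = out.new_record(
                contig=sb.contig, start=sb.pos - 1, alleles=(refb, alt),
                id=f"bnd{n}s",
            )
            rec.qual = round(sb.w, 2)
            rec.filter.add("LOW_QUAL")
            rec.info["SVTYPE"] = "BND"
            out.write(rec)
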