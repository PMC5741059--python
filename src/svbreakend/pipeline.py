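"""End-to-end orchestration: alignments in, break-end VCF out.

Stages (each available separately through the library API):

1. per-file library metrics (:mod:`svbreakend.metrics`);
2. evidence extraction and split-read identification
   (:mod:`svbreakend.evidence`);
3. positional de Bruijn graph assembly per reference contig and break-end
   direction, streamed in coordinate order (:mod:`svbreakend.assembly`);
4. contig realignment into breakpoint evidence, plus direct split-read and
   discordant-pair evidence (:mod:`svbreakend.realign`);
5. maximal-clique variant calling, annotation and confidence
   (:mod:`svbreakend.calling`), written as BND VCF (:mod:`svbreakend.vcf`).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from .align import SeedAligner, SWParams
from .assembly import AssemblyParams, BreakendContig, assemble_streaming
from .breakpoints import BreakpointEvidence, SingleBreakend
from .calling import (
    VariantCall,
    annotate_homology,
    classify_confidence,
    enumerate_maximal_cliques,
    greedy_assign,
)
from .evidence import EvidenceKind, ReadEvidence, extract_evidence, identify_split_reads
from .metrics import LibraryMetrics, collect_metrics
from .placement import PlacedEvidence, base_read_id, evidence_placements
from .realign import evidence_to_breakpoints, realign_contig
from .vcf import write_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    k: int = 25
    min_support: int = 3
    concordance_percentile: float = 0.995
    min_realign_mapq: float = 10.0
    high_qual_threshold: float = 500.0
    ihom_window: int = 300
    max_realign_depth: int = 4
    sw_params: SWParams = field(default_factory=SWParams)
    error_correction: bool = True
    max_base_diff: int = 2


@dataclass
class CallSet:
    calls: list[VariantCall]
    singles: list[SingleBreakend]
    contigs: list[BreakendContig]
    evidence: list[ReadEvidence]
    breakpoints: list[BreakpointEvidence]
    metrics: dict[str, LibraryMetrics]


def load_reference(reference) -> dict[str, str]:
    """Accepts a dict of sequences or a FASTA path."""
    if isinstance(reference, dict):
        return {name: str(seq).upper() for name, seq in reference.items()}
    import pyfaidx

    fa = pyfaidx.Fasta(reference)
    return {name: str(fa[name]).upper() for name in fa.keys()}


def _max_contig_len(metrics_list: list[LibraryMetrics]) -> int:
    hi = max((m.concordant_hi or 600) for m in metrics_list)
    rl = max(m.max_read_length for m in metrics_list)
    return 2 * (hi + rl)


def _constituents(
    support: set[str], by_read: dict[str, list[ReadEvidence]]
) -> list[ReadEvidence]:
    """Representative evidence record per supporting read (split read
    preferred, then soft clip, then pair kinds)."""
    rank = {
        EvidenceKind.SPLIT_READ: 0,
        EvidenceKind.SOFT_CLIP: 1,
        EvidenceKind.INDEL: 2,
        EvidenceKind.DISCORDANT_PAIR: 3,
        EvidenceKind.ONE_END_ANCHOR: 4,
    }
    out = []
    for pid in sorted(support):
        rid = base_read_id(pid)
        records = by_read.get(rid)
        if records:
            out.append(min(records, key=lambda e: rank[e.kind]))
    return out


def assemble_evidence(
    evidence: list[ReadEvidence],
    metrics_by_library: dict[str, LibraryMetrics],
    config: PipelineConfig,
) -> list[BreakendContig]:
    """Run streaming break-end assembly over extracted evidence."""
    placed: dict[tuple[str, str], list[PlacedEvidence]] = {}
    seen_pieces: set[str] = set()
    for ev in evidence:
        m = metrics_by_library[ev.library_id]
        for pe in evidence_placements(ev, m, config.k):
            if pe.placement.read_id in seen_pieces:
                continue
            seen_pieces.add(pe.placement.read_id)
            placed.setdefault((pe.contig, pe.direction), []).append(pe)
    metrics_list = list(metrics_by_library.values())
    params = AssemblyParams(
        k=config.k,
        min_support=config.min_support,
        max_read_length=max(m.max_read_length for m in metrics_list),
        max_contig_len=_max_contig_len(metrics_list),
        max_base_diff=config.max_base_diff,
        error_correction=config.error_correction,
    )
    contigs: list[BreakendContig] = []
    for (contig_name, direction), pes in sorted(placed.items()):
        pes.sort(key=lambda pe: pe.placement.span)
        placements = [pe.placement for pe in pes]
        for c in assemble_streaming(placements, direction, params):
            c.contig = contig_name
            contigs.append(c)
    return contigs


def call_structural_variants(
    alignment_files: list[str],
    reference,
    categories: list[str] | None = None,
    config: PipelineConfig | None = None,
) -> CallSet:
    """The full caller: metrics, extraction, assembly, realignment, calling."""
    config = config or PipelineConfig()
    ref = load_reference(reference)
    if categories is None:
        categories = ["default"] * len(alignment_files)
    metrics_list = [
        collect_metrics(
            path,
            concordance_percentile=config.concordance_percentile,
            library_id=os.path.basename(path),
            category=cat,
        )
        for path, cat in zip(alignment_files, categories)
    ]
    metrics_by_library = {m.library_id: m for m in metrics_list}
    evidence = extract_evidence(alignment_files, metrics_list)
    aligner = SeedAligner(ref, params=config.sw_params)
    evidence = identify_split_reads(evidence, aligner, config.min_realign_mapq)
    by_read: dict[str, list[ReadEvidence]] = {}
    for ev in evidence:
        by_read.setdefault(ev.read_id, []).append(ev)

    contigs = assemble_evidence(evidence, metrics_by_library, config)

    breakpoints = evidence_to_breakpoints(evidence, ref, metrics_by_library)
    dp_breakpoints = [bp for bp in breakpoints if bp.origin == "DP"]
    singles: list[SingleBreakend] = []
    for contig in contigs:
        constituents = _constituents(contig.support, by_read)
        if not constituents:
            continue
        lib = constituents[0].library_id
        bps, sbs = realign_contig(
            contig,
            ref,
            aligner,
            metrics_by_library[lib],
            constituents,
            max_depth=config.max_realign_depth,
            min_mapq=config.min_realign_mapq,
            sw_params=config.sw_params,
            dp_evidence=dp_breakpoints,
        )
        breakpoints.extend(bps)
        singles.extend(sbs)

    cliques = enumerate_maximal_cliques(breakpoints)
    calls = greedy_assign(cliques, breakpoints)
    for call in calls:
        annotate_homology(call, ref, config.ihom_window)
        classify_confidence(call, config.high_qual_threshold)
    return CallSet(
        calls=calls,
        singles=singles,
        contigs=contigs,
        evidence=evidence,
        breakpoints=breakpoints,
        metrics=metrics_by_library,
    )


def run_pipeline(
    alignment_files: list[str],
    reference,
    vcf_path: str,
    categories: list[str] | None = None,
    config: PipelineConfig | None = None,
) -> CallSet:
    result = call_structural_variants(alignment_files, reference, categories, config)
    write_vcf(result.calls, result.singles, load_reference(reference), vcf_path)
    return result
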