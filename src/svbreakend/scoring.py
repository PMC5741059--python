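"""Phred-scaled probabilistic evidence scoring.

Every piece of SV-supporting evidence is scored by the Phred-scaled
probability that it arose from its mapped locations *without* any underlying
structural variant: ``Q = -10 log10 Pr(r)``.  Writing ``M`` for the event
that the mapping is correct,

    Pr(r) = Pr(M) Pr(r|M) + Pr(M̄) Pr(r|M̄),       Pr(r|M̄) = 1,

with ``Pr(M) = (1 - 10^(-mapq_a/10)) (1 - 10^(-mapq_b/10))`` (single-locus
evidence uses only ``mapq_a``).  ``Pr(r|M)`` comes from the library's
empirical distributions:

* split reads / soft clips: the upper-tail mass of the soft-clip length
  distribution at the clip length observed before split-read identification;
* indel-containing reads: the same, using the CIGAR I or D operation length
  distribution;
* read pairs: ``p_d + (1 - p_d) P_rp(ifs)`` where ``p_d`` is the chimeric
  fragment rate and ``P_rp`` the two-sided tail mass of the fragment-size
  distribution at the inferred fragment size; pairs with an unmapped mate
  use ``p_u`` (one-end-unmapped rate) in place of ``p_d`` and have no
  fragment-size term.

Assemblies are scored as the maximum of their constituents' promoted scores
(soft clips promoted to split reads, one-end anchors to discordant pairs),
with the anchored mapping quality taken as the greatest constituent mapping
quality and the unanchored mapping quality from the contig realignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .evidence import EvidenceKind, ReadEvidence
from .metrics import LibraryMetrics

#: Score cap: the model diverges for perfect qualities, so Phred scores are
#: clamped to this value (probabilities below 10^(-q_max/10) are not resolved).
DEFAULT_Q_MAX = 100.0


def phred(p: float, q_max: float = DEFAULT_Q_MAX) -> float:
    """Phred score ``-10 log10(p)`` of a probability, capped at ``q_max``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p!r}")
    if p <= 10.0 ** (-q_max / 10.0):
        return q_max
    q = -10.0 * math.log10(p)
    return q if q > 0.0 else 0.0


def unphred(q: float) -> float:
    """Probability corresponding to a Phred score."""
    return 10.0 ** (-q / 10.0)


def kmer_weight(
    mapq: float, base_quals, start: int, k: int, q_max: float = DEFAULT_Q_MAX
) -> float:
    """Phred weight of the k-mer starting at read offset ``start``.

    The joint probability that every k-mer base was called correctly by the
    sequencer and that the aligner mapped the read to the correct location:

        w(r, i) = -10 log10(1 - (1 - 10^(-mapq/10)) prod_j (1 - 10^(-baseq_j/10)))
    """
    if start < 0 or start + k > len(base_quals):
        raise IndexError("k-mer window outside the read")
    p_ok = 1.0 - unphred(mapq)
    for j in range(start, start + k):
        p_ok *= 1.0 - unphred(base_quals[j])
    return phred(1.0 - p_ok, q_max=q_max)


@dataclass
class EvidenceScore:
    """Phred score of one piece of evidence with its audit components."""

    q: float
    pr_mapping: float = 1.0  # Pr(M)
    pr_given_mapped: float = 1.0  # Pr(r|M)
    components: dict = field(default_factory=dict)


def _pr_mapping(mapq_a: float, mapq_b: float | None) -> float:
    pr = 1.0 - unphred(mapq_a)
    if mapq_b is not None:
        pr *= 1.0 - unphred(mapq_b)
    return pr


def _combine(pr_m: float, pr_given_m: float, q_max: float) -> EvidenceScore:
    pr_r = pr_m * pr_given_m + (1.0 - pr_m) * 1.0
    return EvidenceScore(q=phred(pr_r, q_max=q_max), pr_mapping=pr_m, pr_given_mapped=pr_given_m)


def score_split_read(
    r: ReadEvidence, metrics: LibraryMetrics, q_max: float = DEFAULT_Q_MAX
) -> EvidenceScore:
    """Score a split read (both loci) or a bare soft clip (one locus)."""
    if r.kind not in (EvidenceKind.SPLIT_READ, EvidenceKind.SOFT_CLIP):
        raise ValueError(f"not split-read-like evidence: {r.kind}")
    mapq_b = r.mapq_b if r.kind is EvidenceKind.SPLIT_READ else None
    pr_m = _pr_mapping(r.mapq_a, mapq_b)
    pr_given_m = metrics.softclip_len_dist.upper_tail(r.l_sc)
    return _combine(pr_m, pr_given_m, q_max)


def score_read_pair(
    r: ReadEvidence, metrics: LibraryMetrics, q_max: float = DEFAULT_Q_MAX
) -> EvidenceScore:
    """Score a discordant pair or a one-end anchor.

    One-end anchors have no inferred fragment size: the fragment term is
    omitted and the one-end-unmapped rate ``p_u`` stands in for the chimeric
    fragment rate ``p_d``.
    """
    if r.kind is EvidenceKind.DISCORDANT_PAIR:
        if metrics.fragment_size_dist is None or metrics.p_d is None:
            raise ValueError("fragment size distribution unavailable for this library")
        pr_m = _pr_mapping(r.mapq_a, r.mapq_b)
        if r.ifs is None:
            # interchromosomal / wrong-orientation pair: no fragment size is
            # defined, only the chimeric-fragment term remains
            pr_given_m = metrics.p_d
        else:
            p_rp = metrics.fragment_size_dist.two_sided_tail(r.ifs)
            pr_given_m = metrics.p_d + (1.0 - metrics.p_d) * p_rp
        return _combine(pr_m, pr_given_m, q_max)
    if r.kind is EvidenceKind.ONE_END_ANCHOR:
        pr_m = _pr_mapping(r.mapq_a, None)
        return _combine(pr_m, metrics.p_u, q_max)
    raise ValueError(f"not pair evidence: {r.kind}")


def score_indel_read(
    r: ReadEvidence, metrics: LibraryMetrics, q_max: float = DEFAULT_Q_MAX
) -> EvidenceScore:
    """Score an indel-containing read using the matching I/D length distribution."""
    if r.kind is not EvidenceKind.INDEL:
        raise ValueError(f"not indel evidence: {r.kind}")
    dist = metrics.deletion_len_dist if r.indel_op == "D" else metrics.insertion_len_dist
    pr_m = _pr_mapping(r.mapq_a, None)
    pr_given_m = dist.upper_tail(r.indel_len)
    return _combine(pr_m, pr_given_m, q_max)


def score_evidence(
    r: ReadEvidence, metrics: LibraryMetrics, q_max: float = DEFAULT_Q_MAX
) -> EvidenceScore:
    """Dispatch on evidence kind."""
    if r.kind in (EvidenceKind.SPLIT_READ, EvidenceKind.SOFT_CLIP):
        return score_split_read(r, metrics, q_max)
    if r.kind in (EvidenceKind.DISCORDANT_PAIR, EvidenceKind.ONE_END_ANCHOR):
        return score_read_pair(r, metrics, q_max)
    if r.kind is EvidenceKind.INDEL:
        return score_indel_read(r, metrics, q_max)
    raise ValueError(f"unscorable kind: {r.kind}")


def promote_constituent(r: ReadEvidence) -> ReadEvidence:
    """Promote a constituent read within the context of an assembly.

    Soft clips become split reads and one-end anchors become discordant
    pairs; other kinds pass through unchanged. Promotion happens on a copy.
    """
    import copy

    out = copy.copy(r)
    if r.kind is EvidenceKind.SOFT_CLIP:
        out.kind = EvidenceKind.SPLIT_READ
    elif r.kind is EvidenceKind.ONE_END_ANCHOR:
        out.kind = EvidenceKind.DISCORDANT_PAIR
    return out


def score_assembly(
    constituents: list[ReadEvidence],
    realignment_mapq: float,
    metrics: LibraryMetrics,
    q_max: float = DEFAULT_Q_MAX,
) -> EvidenceScore:
    """Score an assembled contig from its constituent reads.

    The anchored mapping quality is the greatest constituent mapping quality
    and the unanchored mapping quality is the contig realignment's.  The
    assembly score is approximated by the maximum of the promoted constituent
    scores (each constituent rescored with the assembly's mapping qualities).
    """
    if not constituents:
        raise ValueError("assembly has an empty support set")
    import copy

    anchored_mapq = max(c.mapq_a for c in constituents)
    best: EvidenceScore | None = None
    for c in constituents:
        p = promote_constituent(c)
        p = copy.copy(p)
        p.mapq_a = anchored_mapq
        p.mapq_b = realignment_mapq
        if p.kind is EvidenceKind.SPLIT_READ:
            s = score_split_read(p, metrics, q_max)
        elif p.kind is EvidenceKind.DISCORDANT_PAIR:
            if p.ifs is None:  # promoted one-end anchor: no fragment size
                pr_m = _pr_mapping(p.mapq_a, p.mapq_b)
                s = _combine(pr_m, metrics.p_u, q_max)
            else:
                s = score_read_pair(p, metrics, q_max)
        elif p.kind is EvidenceKind.INDEL:
            s = score_indel_read(p, metrics, q_max)
        else:
            continue
        if best is None or s.q > best.q:
            best = s
    if best is None:
        raise ValueError("no scorable constituents in assembly support set")
    return best
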