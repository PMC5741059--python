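"""Per-library alignment metrics.

An initial pass over each coordinate-sorted alignment file collects the
empirical distributions and rates the rest of the pipeline depends on:
fragment-size, soft-clip-length and indel-operation-length distributions,
read/pair counts, concordant fragment-size bounds at the configured
percentile, the chimeric-fragment rate ``p_d`` (pairs whose inferred
fragment size lies more than 10 MADs from the median) and the one-end
unmapped rate ``p_u``.

Fragment sizes are recomputed from the two alignments as the outermost-base
span rather than trusting TLEN (aligner dialects disagree on TLEN sign and
definition), using only both-mapped, same-contig, forward-reverse
inward-facing pairs.  Duplicate, secondary and supplementary alignments are
excluded from all metrics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pysam


@dataclass
class EmpiricalDistribution:
    """Empirical distribution over non-negative integer observations.

    Tail masses floor at ``1/(2 n)`` (a half pseudo-count) so that values
    never seen in the library do not produce infinite Phred scores.
    """

    counts: Counter = field(default_factory=Counter)

    def add(self, value: int, count: int = 1) -> None:
        self.counts[int(value)] += count

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def floor(self) -> float:
        n = self.n
        return 1.0 / (2.0 * n) if n else 1.0

    def mass(self, value: int) -> float:
        n = self.n
        if n == 0:
            return 1.0
        return max(self.counts.get(int(value), 0) / n, self.floor)

    def upper_tail(self, value: int) -> float:
        """P(X >= value), floored."""
        n = self.n
        if n == 0:
            return 1.0
        tail = sum(c for v, c in self.counts.items() if v >= value)
        return min(1.0, max(tail / n, self.floor))

    def two_sided_tail(self, value: int) -> float:
        """P(|X - median| >= |value - median|), floored."""
        n = self.n
        if n == 0:
            return 1.0
        med = self.median()
        dev = abs(value - med)
        tail = sum(c for v, c in self.counts.items() if abs(v - med) >= dev)
        return min(1.0, max(tail / n, self.floor))

    def _sorted_values(self) -> np.ndarray:
        return np.repeat(
            np.fromiter(sorted(self.counts), dtype=float),
            [self.counts[v] for v in sorted(self.counts)],
        )

    def median(self) -> float:
        return float(np.median(self._sorted_values()))

    def mad(self) -> float:
        vals = self._sorted_values()
        return float(np.median(np.abs(vals - np.median(vals))))

    def order_statistic_bounds(self, central_mass: float) -> tuple[int, int]:
        """Closed bounds [lo, hi] of the central ``central_mass`` interval.

        With ``alpha = (1 - central_mass) / 2`` and n observations sorted
        ascending, lo is the ``floor(alpha n)``-th (0-based) order statistic
        and hi its mirror, so at most ``(1 - central_mass) n`` observations
        fall outside [lo, hi].
        """
        vals = self._sorted_values()
        n = len(vals)
        if n == 0:
            raise ValueError("empty distribution")
        alpha = (1.0 - central_mass) / 2.0
        k = int(alpha * n)
        return int(vals[k]), int(vals[n - 1 - k])


@dataclass
class LibraryMetrics:
    library_id: str
    paired: bool = True
    fragment_size_dist: EmpiricalDistribution | None = None
    softclip_len_dist: EmpiricalDistribution = field(default_factory=EmpiricalDistribution)
    insertion_len_dist: EmpiricalDistribution = field(default_factory=EmpiricalDistribution)
    deletion_len_dist: EmpiricalDistribution = field(default_factory=EmpiricalDistribution)
    reads_total: int = 0
    reads_mapped: int = 0
    reads_unmapped: int = 0
    pairs_total: int = 0
    pairs_both_mapped: int = 0
    pairs_one_mapped: int = 0
    pairs_both_unmapped: int = 0
    max_read_length: int = 0
    max_mapped_read_length: int = 0
    concordant_lo: int | None = None
    concordant_hi: int | None = None
    p_d: float | None = None
    p_u: float = 0.0
    category: str = "default"

    @property
    def pair_evidence_available(self) -> bool:
        """False when no mapped pairs were seen; pair-based evidence is then disabled."""
        return self.fragment_size_dist is not None and self.fragment_size_dist.n > 0


def _is_usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_duplicate or read.is_secondary or read.is_supplementary)


def _fr_inward(read: pysam.AlignedSegment) -> bool:
    """True for the leftmost read of a forward-reverse inward-facing same-contig pair."""
    if read.is_unmapped or read.mate_is_unmapped:
        return False
    if read.reference_id != read.next_reference_id:
        return False
    if read.is_reverse or not read.mate_is_reverse:
        return False
    return read.reference_start <= read.next_reference_start


def inferred_fragment_size(read: pysam.AlignedSegment) -> int | None:
    """Outermost-base span of a both-mapped same-contig pair, from the leftmost
    forward read.  Uses the mate CIGAR (MC tag) when available, otherwise the
    read's own length as a stand-in for the mate's aligned span."""
    if not _fr_inward(read):
        return None
    try:
        mc = read.get_tag("MC")
        mate_span = sum(
            length
            for length, op in _cigar_ops(mc)
            if op in "MDN=X"
        )
    except KeyError:
        mate_span = read.infer_query_length() or read.query_length
    mate_end = read.next_reference_start + mate_span  # 0-based exclusive
    return int(mate_end - read.reference_start)


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def collect_metrics(
    alignment_file: str,
    concordance_percentile: float = 0.995,
    library_id: str | None = None,
    category: str = "default",
) -> LibraryMetrics:
    """Single pass over a coordinate-sorted SAM/BAM collecting library metrics.

    ``concordance_percentile`` is the central fragment-size mass considered
    concordant (default 0.995); pairs outside the corresponding order-statistic
    bounds are discordant.
    """
    if not 0.5 < concordance_percentile < 1.0:
        raise ValueError("concordance_percentile must lie in (0.5, 1)")
    m = LibraryMetrics(library_id=library_id or alignment_file, category=category)
    frag = EmpiricalDistribution()
    n_pair_reads_both = n_pair_reads_one = n_pair_reads_none = 0
    any_paired = False
    with pysam.AlignmentFile(alignment_file, require_index=False) as fh:
        if fh.header.get("HD", {}).get("SO") not in (None, "coordinate"):
            raise ValueError(f"{alignment_file}: input must be coordinate-sorted")
        for read in fh:
            if not _is_usable(read):
                continue
            m.reads_total += 1
            qlen = read.query_length or (read.infer_read_length() or 0)
            m.max_read_length = max(m.max_read_length, qlen)
            if read.is_unmapped:
                m.reads_unmapped += 1
            else:
                m.reads_mapped += 1
                m.max_mapped_read_length = max(m.max_mapped_read_length, qlen)
                for op, length in read.cigartuples or []:
                    if op == 4:  # S
                        m.softclip_len_dist.add(length)
                    elif op == 1:  # I
                        m.insertion_len_dist.add(length)
                    elif op == 2:  # D
                        m.deletion_len_dist.add(length)
            if read.is_paired:
                any_paired = True
                if read.is_unmapped and read.mate_is_unmapped:
                    n_pair_reads_none += 1
                elif read.is_unmapped or read.mate_is_unmapped:
                    n_pair_reads_one += 1
                else:
                    n_pair_reads_both += 1
                ifs = inferred_fragment_size(read)
                if ifs is not None:
                    frag.add(ifs)
    if m.reads_total == 0:
        raise ValueError(f"{alignment_file}: no reads")
    m.paired = any_paired
    # Pair categories are tallied per read; each observed pair contributes two
    # records in a complete file, so halve (round up for odd stragglers).
    m.pairs_both_mapped = (n_pair_reads_both + 1) // 2
    m.pairs_one_mapped = (n_pair_reads_one + 1) // 2
    m.pairs_both_unmapped = (n_pair_reads_none + 1) // 2
    m.pairs_total = m.pairs_both_mapped + m.pairs_one_mapped + m.pairs_both_unmapped
    if m.pairs_total:
        m.p_u = m.pairs_one_mapped / m.pairs_total
    if any_paired and frag.n > 0:
        m.fragment_size_dist = frag
        m.concordant_lo, m.concordant_hi = frag.order_statistic_bounds(concordance_percentile)
        med, mad = frag.median(), frag.mad()
        exceeds = sum(
            c for v, c in frag.counts.items() if abs(v - med) > 10.0 * mad
        )
        # Pairs that never produced a well-oriented same-contig fragment size
        # (wrong orientation, different contigs) are chimeric by construction.
        n_anomalous = max(m.pairs_both_mapped - frag.n, 0)
        m.p_d = (exceeds + n_anomalous) / max(frag.n + n_anomalous, 1)
    return m
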