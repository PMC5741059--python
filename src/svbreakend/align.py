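"""Local alignment: affine-gap Smith-Waterman and a seed-and-extend realigner.

The realigner is the pluggable "aligner contract" used for split-read
identification and contig realignment: an exact-seed index over the reference
proposes candidate windows, windowed Smith-Waterman scores them, and a
mapping-quality equivalent is derived from the gap between the best and
second-best window scores (scaled into [0, 60]).  At desk scale this replaces
an external aligner subprocess; an adapter with the same ``align(query)``
surface can be substituted.

Scoring defaults are bwa-like: match +1, mismatch -4, gap open -6, gap
extend -1, where a gap of length L costs ``open + L * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp

try:  # numba accelerates the DP kernel; the pure-python fallback is identical
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


@dataclass(frozen=True)
class SWParams:
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6  # charged once per gap, on top of per-base extension
    gap_extend: int = -1


@dataclass
class Alignment:
    """A local alignment of ``query[query_start:query_end]`` to
    ``ref[ref_start:ref_end]`` (0-based half-open, forward strand of both)."""

    score: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    cigar: list[tuple[str, int]] = field(default_factory=list)

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@njit(cache=True)
def _sw_fill(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    nq, nr = len(q), len(r)
    H = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    E = np.full((nq + 1, nr + 1), -(10**6), dtype=np.int32)
    F = np.full((nq + 1, nr + 1), -(10**6), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, nq + 1):
        for j in range(1, nr + 1):
            e = E[i, j - 1] + gap_extend
            e2 = H[i, j - 1] + gap_open + gap_extend
            E[i, j] = e if e > e2 else e2
            f = F[i - 1, j] + gap_extend
            f2 = H[i - 1, j] + gap_open + gap_extend
            F[i, j] = f if f > f2 else f2
            s = match if q[i - 1] == r[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def smith_waterman(query: str, ref: str, params: SWParams = SWParams()) -> Alignment:
    """Optimal local alignment of ``query`` against ``ref``.

    Ties are broken toward the earliest (query, ref) end cell and, during
    traceback, toward diagonal moves, which keeps results deterministic.
    """
    if not query or not ref:
        raise ValueError("smith_waterman requires nonempty sequences")
    q, r = _encode(query), _encode(ref)
    H, E, F, best, bi, bj = _sw_fill(
        q, r, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    if best <= 0:
        return Alignment(0, 0, 0, 0, 0, [])
    # traceback from (bi, bj)
    i, j = bi, bj
    ops: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = params.match if q[i - 1] == r[j - 1] else params.mismatch
            if h == H[i - 1, j - 1] + s:
                ops.append("M")
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")  # consumes reference
            if E[i, j] == H[i, j - 1] + params.gap_open + params.gap_extend:
                state = "H"
            j -= 1
        else:
            ops.append("I")  # consumes query
            if F[i, j] == H[i - 1, j] + params.gap_open + params.gap_extend:
                state = "H"
            i -= 1
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return Alignment(int(best), i, bi, j, bj, cigar)


@dataclass
class Hit:
    """Best reference placement of a query (coordinates 1-based closed).

    ``query_start``/``query_end`` are 0-based half-open offsets in the query
    as supplied (for '-' strand hits they are mapped back to the original
    orientation).  ``mapq`` is derived from the best-vs-second-best window
    score gap.
    """

    contig: str
    ref_start: int
    ref_end: int
    strand: str
    query_start: int
    query_end: int
    score: int
    mapq: float
    cigar: list[tuple[str, int]] = field(default_factory=list)


class SeedAligner:
    """Seed-and-extend aligner over an in-memory reference.

    Exact ``seed_len``-mers of the reference are indexed once; query seeds
    vote for diagonals, each candidate window is scored with Smith-Waterman,
    and mapq = min(60, mapq_scale * (best - second best)) with 60 when no
    second candidate scores at all.
    """

    def __init__(
        self,
        reference: dict,
        seed_len: int = 12,
        seed_step: int = 4,
        params: SWParams = SWParams(),
        max_candidates: int = 16,
        max_seed_occ: int = 64,
        mapq_scale: float = 4.0,
    ):
        self.reference = {name: str(seq).upper() for name, seq in reference.items()}
        self.seed_len = seed_len
        self.seed_step = seed_step
        self.params = params
        self.max_candidates = max_candidates
        self.max_seed_occ = max_seed_occ
        self.mapq_scale = mapq_scale
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.reference.items():
            for i in range(0, len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], []).append((name, i))

    def _candidates(self, query: str) -> list[tuple[str, int]]:
        """Candidate (contig, window_start) diagonals by seed voting."""
        votes: dict[tuple[str, int], int] = {}
        L = len(query)
        offs = list(range(0, max(L - self.seed_len, 0) + 1, self.seed_step))
        if offs and offs[-1] != L - self.seed_len:
            offs.append(L - self.seed_len)
        for off in offs:
            seed = query[off : off + self.seed_len]
            occs = self._index.get(seed, [])
            if len(occs) > self.max_seed_occ:
                continue
            for contig, pos in occs:
                diag = pos - off
                bucket = diag // 8
                votes[(contig, bucket)] = votes.get((contig, bucket), 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(contig, bucket * 8) for (contig, bucket), _ in ranked[: self.max_candidates]]

    def _window_hits(self, query: str) -> list[tuple[int, str, int, Alignment]]:
        hits = []
        pad = 16 + len(query) // 4
        for contig, diag in self._candidates(query):
            seq = self.reference[contig]
            lo = max(0, diag - pad)
            hi = min(len(seq), diag + len(query) + pad)
            if hi <= lo:
                continue
            aln = smith_waterman(query, seq[lo:hi], self.params)
            if aln.score > 0:
                hits.append((aln.score, contig, lo, aln))
        hits.sort(key=lambda h: (-h[0], h[1], h[2]))
        return hits

    def align(self, query: str) -> Hit | None:
        """Best placement of ``query`` on either strand, or None."""
        if not query:
            return None
        best: Hit | None = None
        scored: list[tuple[int, str, str, int, Alignment]] = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            for score, contig, lo, aln in self._window_hits(q):
                scored.append((score, strand, contig, lo, aln))
        if not scored:
            return None
        scored.sort(key=lambda h: (-h[0], h[2], h[3], h[1]))
        b_score, b_strand, b_contig, b_lo, b_aln = scored[0]

        def orig_qrange(strand, aln):
            if strand == "+":
                return aln.query_start, aln.query_end
            return len(query) - aln.query_end, len(query) - aln.query_start

        bq = orig_qrange(b_strand, b_aln)
        second = 0
        for score, strand, contig, lo, aln in scored[1:]:
            # a competing placement must be genuinely elsewhere on the
            # reference while explaining (mostly) the same query bases
            q = orig_qrange(strand, aln)
            ov = min(bq[1], q[1]) - max(bq[0], q[0])
            if ov < 0.5 * min(bq[1] - bq[0], q[1] - q[0]):
                continue
            if (
                contig != b_contig
                or strand != b_strand
                or abs((lo + aln.ref_start) - (b_lo + b_aln.ref_start)) >= max(8, len(query) // 2)
            ):
                second = score
                break
        if second:
            mapq = max(0.0, min(60.0, self.mapq_scale * (b_score - second)))
        else:
            mapq = 60.0
        qs, qe = b_aln.query_start, b_aln.query_end
        if b_strand == "-":
            qs, qe = len(query) - b_aln.query_end, len(query) - b_aln.query_start
        return Hit(
            contig=b_contig,
            ref_start=b_lo + b_aln.ref_start + 1,
            ref_end=b_lo + b_aln.ref_end,
            strand=b_strand,
            query_start=qs,
            query_end=qe,
            score=b_score,
            mapq=mapq,
            cigar=b_aln.cigar,
        )
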