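"""Positional de Bruijn graph.

Nodes are ``(position, k-mer)`` pairs: a k-mer together with the 1-based
genomic position at which it is expected to occur.  Two nodes are connected
iff their positions differ by exactly one and the last k-1 bases of the
earlier k-mer equal the first k-1 bases of the later one, so the graph is a
DAG and every path is simple.  Each node carries an integer Phred weight
(the rounded sum of supporting k-mer weights — integral rounding makes
aggregation order-independent), an ``anchored`` flag (true iff all k bases
are reference-aligned in some supporting read), and its supporting read set.

Break-ends opening rightwards ('+') are assembled on a *forward* graph in
genome coordinates; break-ends opening leftwards ('-') on a *backward*
graph in reflected coordinates (position -> -position, sequence
reverse-complemented), so a single forward path-calling core serves both
directions.

Placement rules (graph space, forward semantics):

* a clipped read is placed once, at the positions its bases would occupy if
  the entire read were mapped (ungapped projection anchored at the clip-side
  alignment boundary); k-mers fully inside aligned bases are anchored;
* a discordant-pair read is placed, unanchored, at every start position at
  which the pair would be concordant given the mate's anchor and the
  library's concordant fragment-size bounds (closed interval arithmetic:
  with the mate's first base at position ``a`` and fragment sizes in
  ``[lo, hi]``, a read of length L may end at any position in
  ``[a+lo-1, a+hi-1]``, i.e. start in ``[a+lo-L, a+hi-L]``);
* a one-end anchor contributes its mapped read once (anchored, own
  location) and its unmapped mate across the interval implied by the
  mapped read and the fragment-size bounds.

k-mers containing an ambiguous base (N) are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import revcomp
from .scoring import DEFAULT_Q_MAX, kmer_weight

_ALPHABET = "ACGT"


class Node:
    __slots__ = ("weight", "anchored", "support")

    def __init__(self):
        self.weight = 0
        self.anchored = False
        self.support: dict[str, int] = {}

    def __repr__(self):  # pragma: no cover
        return f"Node(w={self.weight}, anchored={self.anchored}, n={len(self.support)})"


@dataclass
class ReadRecord:
    """What the graph remembers about an added read, for k-mer chaining."""

    kmers: list[str | None]  # None where the k-mer contained an N
    starts: list[int]  # placement start positions used


@dataclass
class Placement:
    """A read prepared for graph insertion, already in graph space."""

    read_id: str
    seq: str
    quals: list[int]
    mapq: float
    starts: list[int]
    anchored_qrange: tuple[int, int] | None = None  # half-open read-offset range

    @property
    def span(self) -> tuple[int, int]:
        """Closed node-position span this placement can touch."""
        lo = min(self.starts)
        hi = max(self.starts) + max(len(self.seq) - 1, 0)
        return lo, hi


def edge_exists(x: tuple[int, str], y: tuple[int, str]) -> bool:
    """True iff node y directly follows node x (adjacent k-mers and positions)."""
    (px, sx), (py, sy) = x, y
    return py == px + 1 and sx[1:] == sy[:-1]


class PositionalGraph:
    def __init__(self, k: int, direction: str = "fwd"):
        if not 4 <= k <= 32:
            raise ValueError("k must be in [4, 32]")
        if direction not in ("fwd", "bwd"):
            raise ValueError("direction must be 'fwd' or 'bwd'")
        self.k = k
        self.direction = direction
        self.nodes: dict[tuple[int, str], Node] = {}
        self.read_nodes: dict[str, set[tuple[int, str]]] = {}
        self.reads: dict[str, ReadRecord] = {}

    # -- construction --------------------------------------------------------

    def add_placement(self, pl: Placement, q_max: float = DEFAULT_Q_MAX) -> None:
        """Add one read placement; node weights grow by the rounded k-mer weights."""
        k = self.k
        seq, quals = pl.seq, pl.quals
        if len(seq) < k:
            return
        nkmers = len(seq) - k + 1
        kmers: list[str | None] = []
        weights: list[int] = []
        for i in range(nkmers):
            km = seq[i : i + k]
            if "N" in km or "n" in km:
                kmers.append(None)
                weights.append(0)
                continue
            kmers.append(km)
            weights.append(int(round(kmer_weight(pl.mapq, quals, i, k, q_max=q_max))))
        rid = pl.read_id
        touched = self.read_nodes.setdefault(rid, set())
        rec = self.reads.get(rid)
        if rec is None:
            self.reads[rid] = ReadRecord(kmers=kmers, starts=list(pl.starts))
        else:
            rec.starts.extend(pl.starts)
        aq = pl.anchored_qrange
        single = len(pl.starts) == 1
        for i, km in enumerate(kmers):
            if km is None:
                continue
            w = weights[i]
            anchored = single and aq is not None and aq[0] <= i and i + k <= aq[1]
            for p in pl.starts:
                key = (p + i, km)
                node = self.nodes.get(key)
                if node is None:
                    node = Node()
                    self.nodes[key] = node
                node.weight += w
                node.support[rid] = node.support.get(rid, 0) + w
                if anchored:
                    node.anchored = True
                touched.add(key)

    def add_read_kmers(
        self,
        read_id: str,
        seq: str,
        starts,
        quals=None,
        mapq: float = 40.0,
        anchored_qrange=None,
        q_max: float = DEFAULT_Q_MAX,
    ) -> None:
        """Convenience wrapper: place ``seq`` at every start position in ``starts``."""
        if quals is None:
            quals = [30] * len(seq)
        self.add_placement(
            Placement(read_id, seq, list(quals), mapq, list(starts), anchored_qrange),
            q_max=q_max,
        )

    # -- topology ------------------------------------------------------------

    def successors(self, key: tuple[int, str]) -> list[tuple[int, str]]:
        """Successor nodes, in deterministic (already sorted) k-mer order."""
        p, km = key
        suffix = km[1:]
        out = []
        for b in _ALPHABET:
            nk = (p + 1, suffix + b)
            if nk in self.nodes:
                out.append(nk)
        return out

    def predecessors(self, key: tuple[int, str]) -> list[tuple[int, str]]:
        p, km = key
        prefix = km[:-1]
        out = []
        for b in _ALPHABET:
            nk = (p - 1, b + prefix)
            if nk in self.nodes:
                out.append(nk)
        return out

    def total_weight(self) -> int:
        return sum(n.weight for n in self.nodes.values())

    def is_acyclic(self) -> bool:
        """Trivially true by construction; verifies every edge advances position."""
        return all(
            y[0] == key[0] + 1 for key in self.nodes for y in self.successors(key)
        )

    # -- read removal --------------------------------------------------------

    def remove_read(self, read_id: str) -> None:
        """Remove a read's weight and support from every node it touches."""
        for key in self.read_nodes.pop(read_id, set()):
            node = self.nodes.get(key)
            if node is None:
                continue
            w = node.support.pop(read_id, 0)
            node.weight -= w
            if not node.support:
                del self.nodes[key]
        self.reads.pop(read_id, None)

    # -- merging (error correction support) -----------------------------------

    def merge_node(self, src: tuple[int, str], dst: tuple[int, str]) -> None:
        """Transfer all weight and support of ``src`` into ``dst`` and delete ``src``."""
        a = self.nodes[src]
        b = self.nodes.get(dst)
        if b is None:
            b = Node()
            self.nodes[dst] = b
        b.weight += a.weight
        b.anchored = b.anchored or a.anchored
        for rid, w in a.support.items():
            b.support[rid] = b.support.get(rid, 0) + w
            touched = self.read_nodes.get(rid)
            if touched is not None:
                touched.discard(src)
                touched.add(dst)
        del self.nodes[src]

    # -- dump / load ----------------------------------------------------------

    def dump(self, path: str) -> None:
        """Tab-separated node table: position, kmer, weight, anchored, support."""
        with open(path, "w") as fh:
            fh.write("#position\tkmer\tweight\tanchored\tsupport\n")
            for (pos, km) in sorted(self.nodes):
                node = self.nodes[(pos, km)]
                ids = ",".join(sorted(node.support))
                fh.write(f"{pos}\t{km}\t{node.weight}\t{int(node.anchored)}\t{ids}\n")

    @classmethod
    def load(cls, path: str, k: int, direction: str = "fwd") -> "PositionalGraph":
        g = cls(k, direction)
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                pos, km, w, anch, ids = line.rstrip("\n").split("\t")
                node = Node()
                node.weight = int(w)
                node.anchored = bool(int(anch))
                n_ids = [i for i in ids.split(",") if i]
                for rid in n_ids:
                    node.support[rid] = node.weight // max(len(n_ids), 1)
                    g.read_nodes.setdefault(rid, set()).add((int(pos), km))
                g.nodes[(int(pos), km)] = node
        return g


# -- path-node compression -----------------------------------------------------


@dataclass
class PathNode:
    """Interval- and chain-compressed run of graph nodes.

    Expands to the node set { (p + i, kmer_i, weight_i, anchored) :
    p in [start, end], i in [0, n) } — one parallel chain per start position.
    """

    start: int
    end: int
    kmer_weights: list[tuple[str, int]]
    anchored: bool

    def expand(self) -> dict[tuple[int, str], tuple[int, bool]]:
        out: dict[tuple[int, str], tuple[int, bool]] = {}
        for p in range(self.start, self.end + 1):
            for i, (km, w) in enumerate(self.kmer_weights):
                key = (p + i, km)
                if key in out:
                    out[key] = (out[key][0] + w, out[key][1] or self.anchored)
                else:
                    out[key] = (w, self.anchored)
        return out


def compress(graph: PositionalGraph) -> list[PathNode]:
    """Compress the graph into path nodes.

    Adjacent positions holding the same k-mer with equal weight and anchored
    status collapse into a position interval; branchless chains of interval
    runs (single successor meeting single predecessor, across the whole
    interval) collapse into multi-k-mer path nodes.  ``expand_path_nodes``
    recovers the original node multiset exactly.
    """
    # 1. interval compression per k-mer
    by_kmer: dict[str, list[int]] = {}
    for pos, km in graph.nodes:
        by_kmer.setdefault(km, []).append(pos)
    intervals: list[tuple[int, int, str, int, bool]] = []  # start, end, kmer, w, anchored
    for km, positions in by_kmer.items():
        positions.sort()
        rs = positions[0]
        prev = positions[0]
        sig = graph.nodes[(rs, km)]
        for p in positions[1:]:
            node = graph.nodes[(p, km)]
            same = (
                p == prev + 1
                and node.weight == sig.weight
                and node.anchored == sig.anchored
            )
            if not same:
                intervals.append((rs, prev, km, sig.weight, sig.anchored))
                rs, sig = p, node
            prev = p
        intervals.append((rs, prev, km, sig.weight, sig.anchored))
    # 2. chain compression between aligned interval runs
    by_start: dict[tuple[int, str], tuple[int, int, bool]] = {
        (s, km): (e, w, a) for (s, e, km, w, a) in intervals
    }

    def unique_next(s: int, e: int, km: str):
        """The single following interval run, if every expanded node has a
        unique successor/predecessor across the run; else None."""
        candidates = set()
        for p in range(s, e + 1):
            succ = graph.successors((p, km))
            if len(succ) != 1:
                return None
            nxt = succ[0]
            if len(graph.predecessors(nxt)) != 1:
                return None
            candidates.add(nxt[1])
        if len(candidates) != 1:
            return None
        nkm = candidates.pop()
        nxt_run = by_start.get((s + 1, nkm))
        if nxt_run is None or nxt_run[0] != e + 1:
            return None
        return nkm

    consumed: set[tuple[int, str]] = set()
    out: list[PathNode] = []
    for (s, e, km, w, a) in sorted(intervals):
        if (s, km) in consumed:
            continue
        chain = [(km, w)]
        cs, ce, ckm, ca = s, e, km, a
        while True:
            nkm = unique_next(cs, ce, ckm)
            if nkm is None:
                break
            ne, nw, na = by_start[(cs + 1, nkm)]
            if na != ca:
                break
            consumed.add((cs + 1, nkm))
            chain.append((nkm, nw))
            cs, ce, ckm = cs + 1, ne, nkm
        out.append(PathNode(start=s, end=e, kmer_weights=chain, anchored=a))
    return out


def expand_path_nodes(path_nodes: list[PathNode]) -> dict[tuple[int, str], tuple[int, bool]]:
    out: dict[tuple[int, str], tuple[int, bool]] = {}
    for pn in path_nodes:
        for key, (w, a) in pn.expand().items():
            if key in out:
                out[key] = (out[key][0] + w, out[key][1] or a)
            else:
                out[key] = (w, a)
    return out


def node_multiset(graph: PositionalGraph) -> dict[tuple[int, str], tuple[int, bool]]:
    return {key: (n.weight, n.anchored) for key, n in graph.nodes.items()}


# -- reflection (backward graphs) ----------------------------------------------


def reflect_starts(starts, seq_len: int) -> list[int]:
    """Map genome-space start positions of a read to backward-graph space."""
    return sorted(-(s + seq_len - 1) for s in starts)


def reflect_qrange(qrange, seq_len: int):
    if qrange is None:
        return None
    lo, hi = qrange
    return (seq_len - hi, seq_len - lo)


def make_placement_bwd(
    read_id: str, seq: str, quals, mapq: float, starts, anchored_qrange=None
) -> Placement:
    """Build a backward-graph placement from genome-space read geometry."""
    return Placement(
        read_id=read_id,
        seq=revcomp(seq),
        quals=list(quals)[::-1],
        mapq=mapq,
        starts=reflect_starts(starts, len(seq)),
        anchored_qrange=reflect_qrange(anchored_qrange, len(seq)),
    )
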