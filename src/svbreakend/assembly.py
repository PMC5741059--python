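"""Break-end contig assembly on the positional de Bruijn graph.

A break-end contig is a maximal run of unanchored nodes, optionally flanked
by anchored nodes.  Contigs are called iteratively: the maximally weighted
unanchored path is found by dynamic programming in position order (paths
with an anchored flank are preferred over unflanked ones), extended into
flanking anchored nodes until the anchored length exceeds both the maximum
read length and the unanchored length, truncated by k-mer chaining of its
supporting reads, and emitted; all reads supporting any unanchored k-mer on
the path are then removed from the whole graph, so each read contributes to
a single assembly only.  The loop ends when no unanchored k-mers remain.

Contigs supported by fewer than ``min_support`` reads (default 3), contigs
without an anchored flank shorter than the read length, and contigs longer
than ``max_contig_len`` are filtered (their reads are still consumed).

k-mer-chaining truncation guards against positional looping through repeated
k-mers (a read placed over a position interval can spell a path longer than
itself).  Each supporting read is aligned to the contig placement with the
greatest number of matching k-mers (ties broken toward the truncation-start
side), the k-mer transitions it spells there are marked, and the contig is
re-called as the maximal-weight path using only marked transitions —
equivalently, the path is truncated at the first transition no constituent
read supports.  Truncation is attempted from both ends; the highest-weighted
result is called, preferring paths that retain anchored nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp, spell_path
from .errorcorrect import error_correct
from .graph import Placement, PositionalGraph

MIN_SUPPORT = 3

NEG = float("-inf")


@dataclass
class BreakendContig:
    """An assembled break-end contig in *junction orientation*: the anchored
    flank (possibly empty) first, then the unanchored bases running out of
    the break-end."""

    direction: str  # 'fwd' => '+' break-end, 'bwd' => '-' break-end
    contig: str  # reference contig name ('' until mapped by the pipeline)
    anchored_seq: str
    unanchored_seq: str
    anchor_pos: int | None  # genome position of the last anchored base
    support: set[str] = field(default_factory=set)
    total_weight: int = 0
    graph_span: tuple[int, int] = (0, 0)  # node-position span, graph space

    @property
    def seq_junction(self) -> str:
        return self.anchored_seq + self.unanchored_seq

    @property
    def break_direction(self) -> str:
        return "+" if self.direction == "fwd" else "-"

    @property
    def seq_genome(self) -> str:
        """Contig bases on the reference forward strand."""
        return self.seq_junction if self.direction == "fwd" else revcomp(self.seq_junction)


def maximal_weight_path(
    graph: PositionalGraph, keys=None
) -> list[tuple[int, str]] | None:
    """Maximally weighted path of unanchored nodes with positive support.

    Paths whose first node has an anchored predecessor (anchored-flanked)
    are preferred over unflanked paths; among equals, higher weight wins and
    ties break toward the lexicographically smallest (position, k-mer) end.
    ``keys`` optionally restricts the search to a candidate node subset.
    """
    if keys is None:
        keys = graph.nodes.keys()
    order = sorted(
        key
        for key in keys
        if key in graph.nodes
        and not graph.nodes[key].anchored
        and graph.nodes[key].support
    )
    if not order:
        return None
    best_any: dict[tuple, float] = {}
    best_flk: dict[tuple, float] = {}
    parent_any: dict[tuple, tuple | None] = {}
    parent_flk: dict[tuple, tuple | None] = {}
    usable = set(order)
    for key in order:
        w = graph.nodes[key].weight
        preds = graph.predecessors(key)
        anchored_pred = any(graph.nodes[p].anchored for p in preds)
        ba, pa = w, None
        bf, pf = (w, None) if anchored_pred else (NEG, None)
        for p in preds:
            if p not in usable:
                continue
            cand = best_any[p] + w
            if cand > ba:
                ba, pa = cand, p
            if best_flk[p] != NEG:
                candf = best_flk[p] + w
                if bf == NEG or candf > bf:
                    bf, pf = candf, p
        best_any[key], parent_any[key] = ba, pa
        best_flk[key], parent_flk[key] = bf, pf
    flanked = [k for k in order if best_flk[k] != NEG]
    if flanked:
        end = max(flanked, key=lambda k: (best_flk[k], (-k[0], k[1])))
        parent = parent_flk
    else:
        end = max(order, key=lambda k: (best_any[k], (-k[0], k[1])))
        parent = parent_any
    path = [end]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()
    return path


def extend_into_anchors(
    graph: PositionalGraph, path: list[tuple[int, str]], max_read_length: int
) -> list[tuple[int, str]]:
    """Prepend flanking anchored nodes until the anchored length exceeds both
    the maximum read length and the unanchored path length."""
    unanchored_len = len(path)
    target = max(max_read_length, unanchored_len)
    anchored: list[tuple[int, str]] = []
    cur = path[0]
    while len(anchored) <= target:
        preds = [p for p in graph.predecessors(cur) if graph.nodes[p].anchored]
        if not preds:
            break
        cur = max(preds, key=lambda p: (graph.nodes[p].weight, (-p[0], p[1])))
        anchored.append(cur)
        if len(anchored) > target:
            break
    anchored.reverse()
    return anchored + path


def _read_placement_matches(graph, path_map, rec):
    """For each recorded start of the read, the number of its k-mers matching
    the contig path at that placement."""
    out = []
    for start in sorted(set(rec.starts)):
        m = sum(
            1
            for i, km in enumerate(rec.kmers)
            if km is not None and path_map.get(start + i) == km
        )
        out.append((start, m))
    return out


def truncate_contig(
    graph: PositionalGraph, path: list[tuple[int, str]], supporting_reads=None
) -> list[tuple[int, str]]:
    """k-mer-chaining truncation of a called path (see module docstring)."""
    if len(path) <= 1:
        return path
    if supporting_reads is None:
        supporting_reads = set()
        for key in path:
            supporting_reads.update(graph.nodes[key].support)
    path_map = {pos: km for pos, km in path}
    # choose each read's placement; run twice with opposite tie directions
    results = []
    for tie_toward_start in (True, False):
        transitions: set[tuple[tuple[int, str], tuple[int, str]]] = set()
        matched_nodes: set[tuple[int, str]] = set(path)
        for rid in sorted(supporting_reads):
            rec = graph.reads.get(rid)
            if rec is None:
                continue
            scored = _read_placement_matches(graph, path_map, rec)
            if not scored:
                continue
            best_m = max(m for _, m in scored)
            if best_m == 0:
                continue
            cands = [s for s, m in scored if m == best_m]
            start = min(cands) if tie_toward_start else max(cands)
            prev_key = None
            for i, km in enumerate(rec.kmers):
                if km is None:
                    prev_key = None
                    continue
                key = (start + i, km)
                if key not in graph.nodes:
                    prev_key = None
                    continue
                matched_nodes.add(key)
                if prev_key is not None:
                    transitions.add((prev_key, key))
                prev_key = key
        results.append(_best_supported_path(graph, path, transitions, matched_nodes))
    # prefer anchored-retaining, then heavier, then the start-side run
    def rank(p):
        anchored = any(graph.nodes[key].anchored for key in p if key in graph.nodes)
        weight = sum(graph.nodes[key].weight for key in p if key in graph.nodes)
        return (anchored, weight)

    a, b = results
    return a if rank(a) >= rank(b) else b


def _best_supported_path(graph, path, transitions, allowed_nodes):
    """Max-weight path over read-supported transitions, seeded from the called
    path's node set; falls back to the heaviest single path node."""
    nodes = sorted(allowed_nodes & set(graph.nodes))
    if not nodes:
        return path
    succ_map: dict[tuple, list[tuple]] = {}
    pred_ok: dict[tuple, list[tuple]] = {}
    for a, b in transitions:
        if a in graph.nodes and b in graph.nodes:
            succ_map.setdefault(a, []).append(b)
            pred_ok.setdefault(b, []).append(a)
    best: dict[tuple, float] = {}
    parent: dict[tuple, tuple | None] = {}
    for key in nodes:
        w = graph.nodes[key].weight
        b, p = w, None
        for pr in sorted(pred_ok.get(key, [])):
            if pr in best and best[pr] + w > b:
                b, p = best[pr] + w, pr
        best[key] = b
        parent[key] = p
    end = max(nodes, key=lambda k: (best[k], (-k[0], k[1])))
    out = [end]
    while parent[out[-1]] is not None:
        out.append(parent[out[-1]])
    out.reverse()
    return out


def _build_contig(
    graph: PositionalGraph, path: list[tuple[int, str]], direction: str
) -> tuple[BreakendContig, set[str]]:
    k = graph.k
    n_anchored = 0
    for key in path:
        if graph.nodes[key].anchored:
            n_anchored += 1
        else:
            break
    spelled = spell_path([km for _, km in path])
    anchored_bases = n_anchored + k - 1 if n_anchored else 0
    anchored_seq = spelled[:anchored_bases]
    unanchored_seq = spelled[anchored_bases:]
    unanchored_support: set[str] = set()
    for key in path[n_anchored:]:
        unanchored_support.update(graph.nodes[key].support)
    all_support = set(unanchored_support)
    for key in path[:n_anchored]:
        all_support.update(graph.nodes[key].support)
    weight = sum(graph.nodes[key].weight for key in path)
    start_pos = path[0][0]
    end_pos = path[-1][0] + k - 1
    if direction == "fwd":
        anchor_pos = (path[n_anchored - 1][0] + k - 1) if n_anchored else None
        span = (start_pos, end_pos)
    else:
        # graph space is reflected: genome position of graph base c is -c
        anchor_pos = -(path[n_anchored - 1][0] + k - 1) if n_anchored else None
        span = (-end_pos, -start_pos)
    contig = BreakendContig(
        direction=direction,
        contig="",
        anchored_seq=anchored_seq,
        unanchored_seq=unanchored_seq,
        anchor_pos=anchor_pos,
        support=all_support,
        total_weight=weight,
        graph_span=span,
    )
    return contig, unanchored_support


def _position_clusters(graph: PositionalGraph) -> list[list[tuple[int, str]]]:
    """Partition nodes into runs of contiguous positions; no edge can cross an
    empty position, so clusters are independent for path calling."""
    keys = sorted(graph.nodes)
    clusters: list[list[tuple[int, str]]] = []
    cur: list[tuple[int, str]] = []
    last_pos = None
    for key in keys:
        if last_pos is not None and key[0] > last_pos + 1:
            clusters.append(cur)
            cur = []
        cur.append(key)
        last_pos = key[0]
    if cur:
        clusters.append(cur)
    return clusters


def call_contigs(
    graph: PositionalGraph,
    min_support: int = MIN_SUPPORT,
    max_read_length: int = 100,
    max_contig_len: int | None = None,
) -> list[BreakendContig]:
    """Iteratively call break-end contigs until no unanchored k-mers remain.

    Processing is done per contiguous position cluster (clusters share no
    edges), which keeps repeated maximal-path searches local.
    """
    if max_contig_len is None:
        max_contig_len = 10_000
    out: list[BreakendContig] = []
    for cluster in _position_clusters(graph):
        while True:
            path = maximal_weight_path(graph, cluster)
            if path is None:
                break
            path = extend_into_anchors(graph, path, max_read_length)
            path = truncate_contig(graph, path)
            contig, unanchored_support = _build_contig(graph, path, graph.direction)
            removed = unanchored_support or contig.support
            if not removed:
                break  # defensive: nothing left to consume
            for rid in removed:
                graph.remove_read(rid)
            if len(contig.support) < min_support:
                continue
            if not contig.unanchored_seq:
                continue
            if not contig.anchored_seq and len(contig.unanchored_seq) < max_read_length:
                continue
            if len(contig.seq_junction) > max_contig_len:
                continue
            out.append(contig)
    out.sort(key=lambda c: (c.graph_span, c.seq_junction))
    return out


@dataclass
class AssemblyParams:
    k: int = 25
    min_support: int = MIN_SUPPORT
    max_read_length: int = 100
    max_contig_len: int | None = None
    max_base_diff: int = 2
    error_correction: bool = True


def assemble_region(
    placements: list[Placement], direction: str, params: AssemblyParams
) -> list[BreakendContig]:
    """Whole-graph in-memory assembly of one region."""
    graph = PositionalGraph(params.k, direction)
    for pl in placements:
        graph.add_placement(pl)
    # a single read cannot form a bubble or a spurious leaf against itself
    if params.error_correction and len({pl.read_id for pl in placements}) > 1:
        error_correct(graph, params.max_base_diff, 2 * params.max_read_length)
    return call_contigs(
        graph,
        min_support=params.min_support,
        max_read_length=params.max_read_length,
        max_contig_len=params.max_contig_len,
    )


def assemble_streaming(
    placements: list[Placement],
    direction: str,
    params: AssemblyParams,
    window: int | None = None,
):
    """Streaming assembly: a single in-order pass over placements.

    Placements must be ordered by their minimum node position.  Because a
    read only influences nodes within its own placement span, any position
    gap wider than the streaming window (defaulting to the widest placement
    span plus one k-mer) separates subgraphs that share no nodes or edges;
    each completed subgraph is assembled and its contigs emitted before the
    next one is loaded, so memory is bounded by the densest subgraph and the
    output equals whole-graph assembly exactly.

    Yields contigs as windows complete.  Raises on out-of-order input.
    """
    if window is None:
        spans = [pl.span[1] - pl.span[0] for pl in placements] or [0]
        window = max(spans) + params.k + 1
    chunk: list[Placement] = []
    chunk_max = None
    last_min = None
    for pl in placements:
        lo, hi = pl.span
        if last_min is not None and lo < last_min:
            raise ValueError("placements out of order in streaming assembly")
        last_min = lo
        if chunk and lo > chunk_max + 1:
            yield from assemble_region(chunk, direction, params)
            chunk = []
            chunk_max = None
        chunk.append(pl)
        chunk_max = hi if chunk_max is None else max(chunk_max, hi)
    if chunk:
        yield from assemble_region(chunk, direction, params)
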