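"""Assembly graph error correction: bubble popping and leaf collapse.

Base-calling errors produce low-weight paths running parallel to the true
path.  A path A is collapsed into an alternate path B when its total weight
is lower, the spelled bases differ by fewer than ``max_base_diff`` (default
2, i.e. at most one base), and either

* *bubble*: A and B have the same length and share both their start and end
  node, or
* *leaf*: A shares its start (or end) node with B and terminates in a leaf.

Only paths shorter than ``max_path_len`` (default twice the read length)
are considered.  Collapsing transfers weight and support node-by-node (the
two paths advance one position per edge, so their nodes align by position);
total graph weight is conserved.  Leaf collapse runs before bubble popping
and nodes are visited in deterministic (position, k-mer) order.

Candidate paths are found from fork nodes only; a single census pass counts
every node's in/out degree, so rounds cost one graph scan plus work local to
the forks (alternate paths are explored breadth-first with per-node
memoization of the best partial path, which positions make unambiguous).
"""

from __future__ import annotations

from .graph import PositionalGraph

MAX_BASE_DIFF = 2


class _Census:
    """In/out degree counts, kept current as merges delete source nodes."""

    def __init__(self, graph: PositionalGraph):
        self.graph = graph
        self.out_count: dict[tuple, int] = {}
        self.in_count: dict[tuple, int] = {}
        for key in graph.nodes:
            succ = graph.successors(key)
            self.out_count[key] = len(succ)
            for s in succ:
                self.in_count[s] = self.in_count.get(s, 0) + 1

    def outdeg(self, key) -> int:
        return self.out_count.get(key, 0)

    def indeg(self, key) -> int:
        return self.in_count.get(key, 0)

    def node_deleted(self, key) -> None:
        for s in self.graph.successors(key):
            self.in_count[s] = self.in_count.get(s, 1) - 1
        for p in self.graph.predecessors(key):
            self.out_count[p] = self.out_count.get(p, 1) - 1
        self.out_count.pop(key, None)
        self.in_count.pop(key, None)

    def collapse(self, src_path, dst_path) -> int:
        """Merge src into dst node-by-node; returns number of merges."""
        shared = set(dst_path)
        merges = 0
        for a, b in zip(src_path, dst_path):
            if a == b or a in shared or a not in self.graph.nodes:
                continue
            self.node_deleted(a)
            self.graph.merge_node(a, b)
            merges += 1
        return merges


def _chain_forward(census: _Census, start, limit: int) -> list:
    g = census.graph
    chain = [start]
    cur = start
    while len(chain) < limit:
        if census.outdeg(cur) != 1:
            break
        nxt = g.successors(cur)[0]
        if census.indeg(nxt) != 1:
            break
        chain.append(nxt)
        cur = nxt
    return chain


def _chain_backward(census: _Census, end, limit: int) -> list:
    g = census.graph
    chain = [end]
    cur = end
    while len(chain) < limit:
        if census.indeg(cur) != 1:
            break
        prv = g.predecessors(cur)[0]
        if census.outdeg(prv) != 1:
            break
        chain.append(prv)
        cur = prv
    chain.reverse()
    return chain


def _bases_forward(chain) -> str:
    return "".join(key[1][-1] for key in chain)


def _bases_backward(chain) -> str:
    return "".join(key[1][0] for key in chain)


def _weight(graph, chain) -> int:
    return sum(graph.nodes[key].weight for key in chain)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_parallel(graph, step, fork, first_avoid, length, end=None):
    """Max-weight path of exactly ``length`` nodes from ``fork``'s neighbours
    (via ``step``: successors or predecessors), avoiding ``first_avoid`` as
    the first node and optionally required to finish at ``end``."""
    best: dict[tuple, tuple[int, tuple | None]] = {}
    frontier = []
    for s in step(fork):
        if s == first_avoid:
            continue
        best[s] = (graph.nodes[s].weight, None)
        frontier.append(s)
    for _ in range(length - 1):
        nxt_best: dict[tuple, tuple[int, tuple | None]] = {}
        for node in frontier:
            w, _pred = best[node]
            for s in step(node):
                cand = (w + graph.nodes[s].weight, node)
                if s not in nxt_best or cand[0] > nxt_best[s][0]:
                    nxt_best[s] = cand
        frontier = []
        for node, val in nxt_best.items():
            best[node] = val
            frontier.append(node)
        if not frontier:
            return None
    if not frontier:
        return None
    if end is not None:
        if end not in frontier:
            return None
        final = end
    else:
        final = max(frontier, key=lambda n: (best[n][0], (-n[0], n[1])))
    path = [final]
    cur = final
    while best[cur][1] is not None and len(path) < length:
        cur = best[cur][1]
        path.append(cur)
    if len(path) != length:
        return None
    path.reverse()  # BFS order: first-layer node first
    return path


def pop_bubbles(
    graph: PositionalGraph,
    max_base_diff: int,
    max_path_len: int,
    census: _Census | None = None,
) -> int:
    """Collapse simple bubbles; returns the number of arm merges performed."""
    census = census or _Census(graph)
    merges = 0
    forks = sorted(k for k, c in census.out_count.items() if c >= 2)
    for fork in forks:
        if fork not in graph.nodes or census.outdeg(fork) < 2:
            continue
        for s in graph.successors(fork):
            if s not in graph.nodes:
                continue
            chain = [s]
            cur = s
            merge_node = None
            while len(chain) < max_path_len:
                if census.outdeg(cur) != 1:
                    break
                nxt = graph.successors(cur)[0]
                chain.append(nxt)
                if census.indeg(nxt) > 1:
                    merge_node = nxt  # bubble arm ends here
                    break
                cur = nxt
            if merge_node is None or len(chain) < 2:
                continue
            alt = _best_parallel(
                graph, graph.successors, fork, s, len(chain), end=merge_node
            )
            if alt is None:
                continue
            if _hamming(
                _bases_forward(chain[:-1]), _bases_forward(alt[:-1])
            ) >= max_base_diff:
                continue
            if _weight(graph, chain[:-1]) < _weight(graph, alt[:-1]):
                merges += census.collapse(chain[:-1], alt[:-1])
    return merges


def collapse_leaves(
    graph: PositionalGraph,
    max_base_diff: int,
    max_path_len: int,
    census: _Census | None = None,
) -> int:
    """Collapse terminal leaf paths into heavier parallel paths."""
    census = census or _Census(graph)
    merges = 0
    # forward leaves: fork -> ... -> dead end
    for fork in sorted(k for k, c in census.out_count.items() if c >= 2):
        if fork not in graph.nodes or census.outdeg(fork) < 2:
            continue
        for s in graph.successors(fork):
            if s not in graph.nodes:
                continue
            chain = _chain_forward(census, s, max_path_len)
            if len(chain) >= max_path_len or census.outdeg(chain[-1]):
                continue  # not a terminal leaf within bounds
            alt = _best_parallel(graph, graph.successors, fork, s, len(chain))
            if alt is None:
                continue
            if _hamming(_bases_forward(chain), _bases_forward(alt)) >= max_base_diff:
                continue
            if _weight(graph, chain) < _weight(graph, alt):
                merges += census.collapse(chain, alt)
    # backward leaves: source -> ... -> merge fork
    for fork in sorted(k for k, c in census.in_count.items() if c >= 2):
        if fork not in graph.nodes or census.indeg(fork) < 2:
            continue
        for s in graph.predecessors(fork):
            if s not in graph.nodes:
                continue
            chain = _chain_backward(census, s, max_path_len)
            if len(chain) >= max_path_len or census.indeg(chain[0]):
                continue
            alt = _best_parallel(
                graph, graph.predecessors, fork, s, len(chain)
            )
            if alt is None:
                continue
            alt = list(reversed(alt))
            if _hamming(_bases_backward(chain), _bases_backward(alt)) >= max_base_diff:
                continue
            if _weight(graph, chain) < _weight(graph, alt):
                merges += census.collapse(chain, alt)
    return merges


def error_correct(
    graph: PositionalGraph,
    max_base_diff: int = MAX_BASE_DIFF,
    max_path_len: int | None = None,
    max_rounds: int = 8,
) -> PositionalGraph:
    """Run leaf collapse then bubble popping to a fixed point (bounded rounds)."""
    if max_path_len is None:
        max_path_len = 200
    census = _Census(graph)  # kept current through merges, so built once
    if not any(c >= 2 for c in census.out_count.values()) and not any(
        c >= 2 for c in census.in_count.values()
    ):
        return graph
    for _ in range(max_rounds):
        changed = collapse_leaves(graph, max_base_diff, max_path_len, census)
        changed += pop_bubbles(graph, max_base_diff, max_path_len, census)
        if not changed:
            break
    return graph
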