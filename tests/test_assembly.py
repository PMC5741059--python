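"""Break-end contig calling, truncation, and streaming assembly."""

import numpy as np
import pytest

from svbreakend._util import spell_path
from svbreakend.assembly import (
    AssemblyParams,
    assemble_region,
    assemble_streaming,
    call_contigs,
    maximal_weight_path,
    truncate_contig,
)
from svbreakend.graph import Placement, PositionalGraph


def spelled(path):
    return spell_path([km for _, km in path])


class TestRepeatLooping:
    """The positional-loop misassembly and its k-mer-chaining cure: a single
    read with a repeated k-mer placed over a position window spells a path
    longer than itself; chaining truncates it back to the read."""

    def test_repeated_kmer_loops_through_placement_window(self):
        g = PositionalGraph(4)
        g.add_read_kmers("r", "TAAAAC", starts=range(10, 15))
        path = maximal_weight_path(g)
        assert path[0][0] == 10
        assert spelled(path) == "TAAAAAAAAC"

    def test_chaining_truncates_to_the_read(self):
        g = PositionalGraph(4)
        g.add_read_kmers("r", "TAAAAC", starts=range(10, 15))
        path = truncate_contig(g, maximal_weight_path(g))
        assert spelled(path) == "TAAAAC"

    def test_path_spelled_by_single_read_unchanged(self):
        g = PositionalGraph(4)
        g.add_read_kmers("r", "ACGGTCAT", starts=[50])
        path = maximal_weight_path(g)
        assert truncate_contig(g, path) == path
        assert spelled(path) == "ACGGTCAT"

    def test_two_staggered_agreeing_reads_unchanged(self):
        seq = "ACGGTCATTGCAAGGT"
        g = PositionalGraph(4)
        g.add_read_kmers("a", seq[:12], starts=[50])
        g.add_read_kmers("b", seq[4:], starts=[54])
        path = maximal_weight_path(g)
        assert spelled(path) == seq
        assert truncate_contig(g, path) == path


def clip_reads(g, seq, start, n, anchored_len, prefix="r"):
    for i in range(n):
        g.add_read_kmers(
            f"{prefix}{i}", seq, starts=[start], anchored_qrange=(0, anchored_len)
        )


class TestCallContigs:
    def test_three_identical_clipped_reads_make_one_contig(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=50))  # 30M20S
        g = PositionalGraph(25)
        clip_reads(g, seq, 1000, 3, anchored_len=30)
        contigs = call_contigs(g, min_support=3, max_read_length=50)
        assert len(contigs) == 1
        c = contigs[0]
        assert c.unanchored_seq == seq[30:]
        assert c.anchored_seq == seq[:30]
        assert c.anchor_pos == 1029
        assert len(c.support) == 3

    def test_below_min_support_is_filtered(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=50))
        g = PositionalGraph(25)
        clip_reads(g, seq, 1000, 2, anchored_len=30)
        assert call_contigs(g, min_support=3, max_read_length=50) == []

    def test_no_supported_unanchored_kmers_remain_after_termination(self, rng):
        bases = np.array(list("ACGT"))
        g = PositionalGraph(25)
        for j in range(3):
            seq = "".join(rng.choice(bases, size=50))
            clip_reads(g, seq, 1000 + 200 * j, 3, anchored_len=30, prefix=f"g{j}_")
        call_contigs(g, min_support=3, max_read_length=50)
        assert not any(
            n.support for key, n in g.nodes.items() if not n.anchored
        )

    def test_reads_partition_across_contigs(self, rng):
        bases = np.array(list("ACGT"))
        g = PositionalGraph(25)
        for j in range(4):
            seq = "".join(rng.choice(bases, size=50))
            clip_reads(g, seq, 1000 + 300 * j, 4, anchored_len=30, prefix=f"g{j}_")
        contigs = call_contigs(g, min_support=3, max_read_length=50)
        seen = set()
        for c in contigs:
            assert not (c.support & seen)
            seen |= c.support

    def test_empty_graph_gives_empty_list(self):
        assert call_contigs(PositionalGraph(25)) == []


def enumerate_unanchored_paths(g):
    """Exhaustive oracle: every maximal-by-extension path of supported
    unanchored nodes, via DFS."""
    nodes = [k for k, n in g.nodes.items() if not n.anchored and n.support]
    node_set = set(nodes)
    paths = []

    def extend(path):
        last = path[-1]
        nxt = [s for s in g.successors(last) if s in node_set]
        if not nxt:
            paths.append(list(path))
            return
        for s in nxt:
            path.append(s)
            extend(path)
            path.pop()

    starts = [
        k for k in nodes
        if not any(p in node_set for p in g.predecessors(k))
    ]
    for s in starts:
        extend([s])
    return paths


class TestMaximalityOracle:
    def test_matches_exhaustive_enumeration_on_random_graphs(self, rng):
        bases = np.array(list("ACGT"))
        for trial in range(15):
            g = PositionalGraph(4)
            n_reads = int(rng.integers(2, 7))
            for i in range(n_reads):
                seq = "".join(rng.choice(bases, size=int(rng.integers(4, 12))))
                start = int(rng.integers(0, 25))
                width = int(rng.integers(1, 4))
                g.add_read_kmers(f"r{i}", seq, starts=range(start, start + width))
            if len(g.nodes) > 200:
                continue
            path = maximal_weight_path(g)
            oracle_paths = enumerate_unanchored_paths(g)
            if path is None:
                assert not oracle_paths
                continue
            w = lambda p: sum(g.nodes[k].weight for k in p)
            # oracle considers every contiguous subpath; the DFS already covers
            # maximal ones and subpaths can never weigh more (weights >= 0)
            assert w(path) == max(w(p) for p in oracle_paths)


def _params(**kw):
    defaults = dict(k=25, min_support=3, max_read_length=50, max_contig_len=5000)
    defaults.update(kw)
    return AssemblyParams(**defaults)


def random_region_placements(rng, n_junctions=3, spacing=5000):
    bases = np.array(list("ACGT"))
    placements = []
    for j in range(n_junctions):
        seq = "".join(rng.choice(bases, size=50))
        base_pos = 1000 + spacing * j
        n = int(rng.integers(3, 7))
        for i in range(n):
            placements.append(
                Placement(
                    read_id=f"j{j}r{i}",
                    seq=seq,
                    quals=[30] * 50,
                    mapq=60.0,
                    starts=[base_pos],
                    anchored_qrange=(0, 30),
                )
            )
        # plus a mate-placed read over an interval
        placements.append(
            Placement(
                read_id=f"j{j}dp",
                seq=seq[20:],
                quals=[30] * 30,
                mapq=60.0,
                starts=list(range(base_pos + 10, base_pos + 40)),
                anchored_qrange=None,
            )
        )
    placements.sort(key=lambda p: p.span)
    return placements


class TestStreaming:
    def test_single_window_identical_to_whole_graph(self, rng):
        placements = random_region_placements(rng, n_junctions=1)
        whole = assemble_region(placements, "fwd", _params())
        streamed = list(assemble_streaming(placements, "fwd", _params()))
        assert [(c.seq_junction, sorted(c.support)) for c in whole] == [
            (c.seq_junction, sorted(c.support)) for c in streamed
        ]

    def test_distant_junctions_match_per_region_assembly(self, rng):
        placements = random_region_placements(rng, n_junctions=3, spacing=1_000_000)
        streamed = list(assemble_streaming(placements, "fwd", _params()))
        whole = assemble_region(placements, "fwd", _params())
        key = lambda cs: sorted((c.seq_junction, tuple(sorted(c.support))) for c in cs)
        assert key(streamed) == key(whole)
        assert len(streamed) == 3

    def test_out_of_order_evidence_raises(self, rng):
        placements = random_region_placements(rng, n_junctions=2)
        placements.reverse()
        with pytest.raises(ValueError, match="out of order"):
            list(assemble_streaming(placements, "fwd", _params()))

    def test_concordant_only_input_is_empty(self):
        assert list(assemble_streaming([], "fwd", _params())) == []
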