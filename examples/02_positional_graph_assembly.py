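"""The positional de Bruijn graph and its repeat-looping failure mode.

A read whose placement is only known to an interval (like the mate of a
discordant pair) is added at every admissible start position.  If the read
contains a repeated k-mer, the maximal-weight path can loop through the
repeat for as long as the placement window allows, spelling a contig longer
than the read.  k-mer chaining of the supporting reads truncates the path at
the first transition no read supports.
"""

from svbreakend import PositionalGraph, maximal_weight_path, truncate_contig
from svbreakend._util import spell_path

graph = PositionalGraph(k=4)
# the read TAAAAC may start anywhere in a 5-position window
graph.add_read_kmers("read1", "TAAAAC", starts=range(10, 15))
print(f"graph: {len(graph.nodes)} (position, k-mer) nodes")

path = maximal_weight_path(graph)
seq = spell_path([km for _, km in path])
print(f"maximal-weight path: {seq!r} starting at position {path[0][0]}")
print("  -> the AAAA k-mer exists at five consecutive positions, so the path")
print("     loops through it and spells four extra A's the read never had")

truncated = truncate_contig(graph, path)
seq_t = spell_path([km for _, km in truncated])
print(f"after k-mer chaining truncation: {seq_t!r} at position {truncated[0][0]}")
print("  -> only transitions spelled by an actual supporting read are kept,")
print("     restoring the read sequence itself")
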