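"""Small shared helpers: sequence manipulation and coordinate conventions.

Coordinates are 1-based and fully closed throughout the package, matching
SAM/VCF. A break-end is written ``(contig, pos, direction)`` where direction
``'+'`` means the retained sequence lies at or before ``pos`` (the junction
opens to the right) and ``'-'`` means the retained sequence lies at or after
``pos`` (the junction opens to the left).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def kmers_of(seq: str, k: int) -> list[str]:
    """All k-mers of ``seq`` in order; empty if the sequence is shorter than k."""
    if len(seq) < k:
        return []
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def spell_path(kmer_chain: list[str]) -> str:
    """Bases spelled by a chain of position-adjacent k-mers."""
    if not kmer_chain:
        return ""
    return kmer_chain[0] + "".join(km[-1] for km in kmer_chain[1:])


def genome_order_key(contig: str, pos: int) -> tuple[str, int]:
    return (contig, pos)
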