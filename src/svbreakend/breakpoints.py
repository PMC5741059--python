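"""Breakpoint evidence: the support tuple aggregated by variant calling.

A piece of breakpoint evidence is the tuple (s_l, e_l, s_h, e_h, d_l, d_h, w):
the genome intervals between which a breakpoint is supported on its lower and
higher side, the break-end directions, and the Phred weight from the scoring
model.  Evidence is normalised so the lower break-end sorts first in genome
order; swapping sides reverse-complements any untemplated sequence (the
junction is then read from the other direction).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import revcomp


@dataclass
class BreakpointEvidence:
    contig_l: str
    s_l: int
    e_l: int
    d_l: str
    contig_h: str
    s_h: int
    e_h: int
    d_h: str
    w: float
    origin: str  # 'SR' | 'DP' | 'ASSEMBLY'
    category: str = "default"
    read_ids: frozenset = frozenset()
    untemplated_seq: str = ""
    exact: bool = False  # single-base junction resolution (SR / assembly)
    nominal_l: int | None = None
    nominal_h: int | None = None
    assembly_side: str | None = None  # 'lo'/'hi': break-end the contig anchors

    def __post_init__(self):
        if self.s_l > self.e_l or self.s_h > self.e_h:
            raise ValueError("invalid breakpoint interval")
        if (self.contig_l, self.s_l) > (self.contig_h, self.s_h):
            self._swap()

    def _swap(self) -> None:
        self.contig_l, self.contig_h = self.contig_h, self.contig_l
        self.s_l, self.s_h = self.s_h, self.s_l
        self.e_l, self.e_h = self.e_h, self.e_l
        self.d_l, self.d_h = self.d_h, self.d_l
        self.nominal_l, self.nominal_h = self.nominal_h, self.nominal_l
        self.untemplated_seq = revcomp(self.untemplated_seq)
        if self.assembly_side is not None:
            self.assembly_side = "hi" if self.assembly_side == "lo" else "lo"

    @property
    def subset(self) -> tuple[str, str, str, str]:
        """Directional subset key: evidence can only mutually support a
        breakpoint if contigs and both directions match."""
        return (self.contig_l, self.contig_h, self.d_l, self.d_h)

    def overlaps(self, other: "BreakpointEvidence") -> bool:
        return (
            self.subset == other.subset
            and self.s_l <= other.e_l
            and other.s_l <= self.e_l
            and self.s_h <= other.e_h
            and other.s_h <= self.e_h
        )


@dataclass
class SingleBreakend:
    """A break-end whose partner could not be located (unaligned residue)."""

    contig: str
    pos: int
    direction: str
    w: float
    inserted_seq: str = ""
    read_ids: frozenset = frozenset()
    category: str = "default"
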