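import numpy as np
import pysam
import pytest

from svbreakend.metrics import EmpiricalDistribution, LibraryMetrics


def make_header(contigs=None):
    contigs = contigs or {"chr1": 100_000}
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()],
        }
    )


def sam_pair_line(name, flag, contig, pos1, mapq, cigar, mate_pos, tlen, seq, qual="*", tags=()):
    fields = [
        name, str(flag), contig, str(pos1), str(mapq), cigar,
        "=", str(mate_pos), str(tlen), seq,
        qual if qual != "*" else ("I" * len(seq) if seq != "*" else "*"),
    ]
    fields.extend(tags)
    return "\t".join(fields)


def write_sam(path, lines, contigs=None):
    contigs = contigs or {"chr1": 100_000}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, ln in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for line in lines:
            fh.write(line + "\n")
    return str(path)


def make_fr_pair(name, contig, pos1, frag, read_len=100, mapq=60, seq=None):
    """SAM lines for a concordant forward-reverse pair with the given
    outermost-span fragment size."""
    seq = seq or ("A" * read_len)
    pos2 = pos1 + frag - read_len
    cig = f"{read_len}M"
    l1 = sam_pair_line(name, 99, contig, pos1, mapq, cig, pos2, frag, seq,
                       tags=(f"MC:Z:{cig}", f"MQ:i:{mapq}"))
    l2 = sam_pair_line(name, 147, contig, pos2, mapq, cig, pos1, -frag, seq,
                       tags=(f"MC:Z:{cig}", f"MQ:i:{mapq}"))
    return [l1, l2]


def const_dist(values):
    d = EmpiricalDistribution()
    for v in values:
        d.add(v)
    return d


class StubDist:
    """Distribution stub with fixed tail masses, for scoring-model examples."""

    def __init__(self, upper=1.0, two_sided=1.0):
        self._upper = upper
        self._two = two_sided

    def upper_tail(self, value):
        return self._upper

    def two_sided_tail(self, value):
        return self._two


def stub_metrics(
    p_d=0.0,
    p_u=0.0,
    sc_tail=1.0,
    rp_tail=1.0,
    ins_tail=1.0,
    del_tail=1.0,
    concordant=(250, 350),
    max_read_length=100,
):
    m = LibraryMetrics(library_id="stub")
    m.softclip_len_dist = StubDist(upper=sc_tail)
    m.insertion_len_dist = StubDist(upper=ins_tail)
    m.deletion_len_dist = StubDist(upper=del_tail)
    m.fragment_size_dist = StubDist(two_sided=rp_tail)
    m.fragment_size_dist.n = 1000  # quacks enough for availability checks
    m.p_d = p_d
    m.p_u = p_u
    m.concordant_lo, m.concordant_hi = concordant
    m.max_read_length = max_read_length
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
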