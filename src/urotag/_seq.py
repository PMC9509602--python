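"""Low-level sequence helpers shared by the digestion, QC and simulation code."""

from __future__ import annotations

from typing import NamedTuple

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Tag geometry: 32 bp total, 12-bp recognition core at 0-based offset 10.
TAG_LENGTH = 32
CORE_OFFSET = 10
#: Forward-strand core: CGA-N6-TGC. Its reverse complement reads GCA-N6-TCG.
CORE_FWD = ("CGA", "TGC")
CORE_REV = ("GCA", "TCG")


class Read(NamedTuple):
    """A single-end sequencing read with a Phred+33 quality string."""

    id: str
    sequence: str
    quality: str


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Canonical orientation: the lexicographically smaller of seq / revcomp."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def has_core_motif(seq32: str) -> bool:
    """True if a 32-mer carries the recognition core in either orientation.

    The core triplets must match exactly; an N anywhere inside them matches
    nothing, so N-containing cores fail.
    """
    if len(seq32) != TAG_LENGTH:
        return False
    a = seq32[CORE_OFFSET : CORE_OFFSET + 3]
    b = seq32[CORE_OFFSET + 9 : CORE_OFFSET + 12]
    return (a, b) in (CORE_FWD, CORE_REV)


def phred_char(q: int) -> str:
    """Phred+33 encoding of an integer quality, clipped to the sane 0..41 range."""
    return chr(33 + max(0, min(41, q)))
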