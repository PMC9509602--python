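"""Enzyme-read extraction and quality filtering.

Raw reads are first reduced to "enzyme reads" — 32-bp reads carrying the
BcgI recognition core (CGA at positions 11-13 and TGC at 20-22, 1-based, in
either orientation), i.e. genuine digested fragments.  Clean reads are then
obtained by removing reads with more than 8% unknown bases and reads in
which more than 20% of bases have quality Q <= 20.  Both boundaries are
strict (a read at exactly 8% or exactly 20% survives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._seq import Read, has_core_motif

__all__ = ["QCReport", "MalformedReadError", "extract_enzyme_reads", "qc_filter", "run_qc"]

MAX_N_FRACTION = 0.08
MAX_LOWQ_FRACTION = 0.20
LOW_QUALITY_Q = 20  # Q <= 20 counts as low quality (inclusive)


class MalformedReadError(ValueError):
    """A record whose quality string cannot be interpreted, named by read id."""


@dataclass
class QCReport:
    n_raw: int
    n_enzyme: int
    n_clean: int
    removed_by_n: int = 0
    removed_by_quality: int = 0

    def __post_init__(self) -> None:
        if not self.n_raw >= self.n_enzyme >= self.n_clean >= 0:
            raise ValueError("QC counts must satisfy n_raw >= n_enzyme >= n_clean >= 0")

    @property
    def fraction_enzyme(self) -> float:
        return self.n_enzyme / self.n_raw if self.n_raw else 0.0

    @property
    def fraction_clean(self) -> float:
        return self.n_clean / self.n_raw if self.n_raw else 0.0


def extract_enzyme_reads(reads: Sequence[Read]) -> list[Read]:
    """Keep reads carrying the recognition core in either orientation.

    Reads whose length is not 32 are discarded (counted by the caller via
    the report), not an error.  N inside a core triplet matches nothing.
    """
    return [r for r in reads if has_core_motif(r.sequence)]


def _fails_filters(
    read: Read,
    max_n_fraction: float,
    max_lowq_fraction: float,
    low_quality_q: int,
) -> str | None:
    seq, qual = read.sequence, read.quality
    if len(qual) != len(seq) or any(c < "!" for c in qual):
        raise MalformedReadError(f"malformed quality string for read {read.id!r}")
    n = len(seq)
    if seq.count("N") / n > max_n_fraction:
        return "n"
    low_q = sum(1 for c in qual if ord(c) - 33 <= low_quality_q)
    if low_q / n > max_lowq_fraction:
        return "quality"
    return None


def qc_filter(
    reads: Sequence[Read],
    max_n_fraction: float = MAX_N_FRACTION,
    max_lowq_fraction: float = MAX_LOWQ_FRACTION,
    low_quality_q: int = LOW_QUALITY_Q,
) -> tuple[list[Read], QCReport]:
    """Apply the two clean-read filters, preserving order.

    Removal is attributed to the unknown-base filter first; reads failing
    only the low-quality filter are attributed to it, so the report's
    counts partition the input.
    """
    clean: list[Read] = []
    removed = {"n": 0, "quality": 0}
    for r in reads:
        reason = _fails_filters(r, max_n_fraction, max_lowq_fraction, low_quality_q)
        if reason is None:
            clean.append(r)
        else:
            removed[reason] += 1
    n_in = len(reads)
    report = QCReport(
        n_raw=n_in,
        n_enzyme=n_in,
        n_clean=len(clean),
        removed_by_n=removed["n"],
        removed_by_quality=removed["quality"],
    )
    return clean, report


def run_qc(
    reads: Sequence[Read],
    max_n_fraction: float = MAX_N_FRACTION,
    max_lowq_fraction: float = MAX_LOWQ_FRACTION,
    low_quality_q: int = LOW_QUALITY_Q,
) -> tuple[list[Read], QCReport]:
    """Full raw -> enzyme -> clean pass with a per-sample report."""
    enzyme = extract_enzyme_reads(reads)
    clean, rep = qc_filter(enzyme, max_n_fraction, max_lowq_fraction, low_quality_q)
    return clean, QCReport(
        n_raw=len(reads),
        n_enzyme=len(enzyme),
        n_clean=len(clean),
        removed_by_n=rep.removed_by_n,
        removed_by_quality=rep.removed_by_quality,
    )
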