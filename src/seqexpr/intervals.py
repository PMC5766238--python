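"""Half-open genomic interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` on a single
chromosome.  These primitives back the region derivation (promoter
segmentation, intron subtraction) and the interval-density statistics, so
they are implemented directly rather than through a heavier interval
library: every operation here has an exact positional oracle used in the
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def merge(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping or bookended intervals (BedTools-merge semantics).

    ``[10,20)`` and ``[20,30)`` merge into ``[10,30)``.  Input intervals
    must share one chromosome and strand.
    """
    if not intervals:
        return []
    _check_same_context(intervals)
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.start <= last.end:  # overlap or bookended
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            out.append(iv)
    return out


def subtract(
    span: GenomicInterval, remove: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference ``span \\ union(remove)`` as maximal disjoint intervals."""
    merged = merge([iv for iv in remove if iv.end > span.start and iv.start < span.end])
    out: list[GenomicInterval] = []
    cursor = span.start
    for iv in merged:
        lo = max(iv.start, span.start)
        if lo > cursor:
            out.append(GenomicInterval(span.chrom, cursor, lo, span.strand))
        cursor = max(cursor, min(iv.end, span.end))
    if cursor < span.end:
        out.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    return out


def intersect_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def clip(
    chrom: str, start: int, end: int, chrom_length: int, strand: str = "+"
) -> GenomicInterval | None:
    """Clip raw coordinates to ``[0, chrom_length)``; ``None`` if empty."""
    lo = max(0, start)
    hi = min(end, chrom_length)
    if lo >= hi:
        return None
    return GenomicInterval(chrom, lo, hi, strand)


def _check_same_context(intervals: Sequence[GenomicInterval]) -> None:
    chroms = {iv.chrom for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError(
            f"intervals span multiple contexts: chroms={sorted(chroms)}, "
            f"strands={sorted(strands)}"
        )
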