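"""Genomic interval primitives shared by every pipeline stage.

All coordinates inside the package are 0-based half-open ``[start, end)``.
1-based inclusive inputs (GFF3, CNVnator call files) are converted at the
I/O boundary; BED input passes through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "GenomicInterval",
    "overlap_bp",
    "overlap_fractions",
    "length_mbp",
    "round_half_up",
    "subgenome",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom :
        Chromosome or scaffold name, e.g. ``"chrA01"``.
    start :
        0-based inclusive start (bp).
    end :
        Exclusive end (bp); must satisfy ``end > start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "end must be greater than start"
            )
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fractions(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap expressed as a fraction of each interval's own length.

    Returns ``(ovl / len(a), ovl / len(b))`` — the quantities thresholded by
    reciprocal-overlap filters (bedtools ``-f ... -r`` semantics).
    """
    ovl = overlap_bp(a, b)
    return ovl / a.length, ovl / b.length


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties going away from zero, as printed reports do.

    Python's builtin ``round`` uses banker's rounding; reported percentages
    and Mbp lengths here follow the conventional half-up rule instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def length_mbp(iv: GenomicInterval, decimals: int = 2) -> float:
    """Interval length in Mbp, rounded half-up to ``decimals`` places."""
    return round_half_up(iv.length / 1e6, decimals)


_SUBGENOME_RE = re.compile(r"^(chr)?([AC])\d", re.IGNORECASE)


def subgenome(chrom: str) -> str | None:
    """Map a chromosome name to its sub-genome label.

    *B. napus* is an allopolyploid: chromosomes A01..A10 derive from
    *B. rapa* (A sub-genome) and C01..C09 from *B. oleracea* (C sub-genome).
    Both the ``A01`` and ``chrA01`` dialects are accepted, case-insensitively.
    Unscaffolded or otherwise unrecognised names return ``None`` and are
    excluded from sub-genome tallies.
    """
    m = _SUBGENOME_RE.match(chrom)
    if m is None:
        return None
    return m.group(2).upper()
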