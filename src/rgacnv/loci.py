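"""Resistance-locus anchoring from markers and per-locus RGA breakdowns.

Blackleg resistance loci (Rlm/LepR) are delimited by genetic markers. A
marker is placed on the reference either from explicit coordinates or by
exact matching of its primer pair (forward primer and reverse-complemented
reverse primer on the same chromosome within a maximum amplicon span). The
locus region is the union span of its marker hits; RGAs overlapping the
region by ≥1 bp are candidates, and candidates with ≥1 CNV event are
"affected".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cnv_genes import GeneCnvEvent, gene_status
from .intervals import GenomicInterval, length_mbp, overlap_bp
from .io import MarkerRow, GeneRecord
from .rga import RGA_LABELS, RgaClass

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerHit",
    "LocusRegion",
    "locate_primer_pair",
    "locate_markers",
    "build_locus",
    "locus_breakdown",
    "qtl_table",
]

#: Display order for subclass labels in breakdown strings.
_CLASS_ORDER = ("NBS", "TNL", "TN", "CNL", "CN", "NL", "TX", "OTHER", "RLK", "RLP")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


@dataclass(frozen=True)
class MarkerHit:
    """A marker placed on the reference: the amplicon (or given) span."""

    locus: str
    marker_name: str
    interval: GenomicInterval


@dataclass(frozen=True)
class LocusRegion:
    """A resistance locus: the union span of its marker hits."""

    locus: str
    chrom: str
    interval: GenomicInterval

    @property
    def length_mbp(self) -> float:
        return length_mbp(self.interval)


def locate_primer_pair(
    fwd: str,
    rev: str,
    reference: Mapping[str, str],
    locus: str = "",
    marker_name: str = "",
    max_span: int = 10_000,
) -> MarkerHit | None:
    """Place a primer pair by exact matching on the reference.

    The amplicon requires the forward primer and the reverse-complement of
    the reverse primer on the same chromosome, in order, within
    ``max_span`` bp; the swapped orientation (pair amplifying off the other
    strand) is also considered. Exactly one compatible placement must exist;
    zero or several yield ``None`` with the reason logged.
    """
    for name, primer in (("forward", fwd), ("reverse", rev)):
        if len(primer) < 15:
            raise ValueError(f"{name} primer shorter than 15 bp")
        if set(primer) - set("ACGT"):
            raise ValueError(f"{name} primer has characters outside ACGT: {primer!r}")

    amplicons: list[GenomicInterval] = []
    for left, right in ((fwd, _revcomp(rev)), (rev, _revcomp(fwd))):
        for chrom, seq in reference.items():
            for s in _find_all(seq, left):
                for e0 in _find_all(seq, right):
                    end = e0 + len(right)
                    if end > s and end - s <= max_span:
                        amplicons.append(GenomicInterval(chrom, s, end))
    amplicons = sorted(set(amplicons))
    if len(amplicons) != 1:
        logger.info(
            "marker %s/%s: %d compatible placements, expected exactly 1",
            locus, marker_name, len(amplicons),
        )
        return None
    return MarkerHit(locus, marker_name, amplicons[0])


def locate_markers(
    rows: Sequence[MarkerRow],
    reference: Mapping[str, str] | None = None,
    max_span: int = 10_000,
) -> list[MarkerHit]:
    """Place every marker row; explicit coordinates take precedence over
    primers. Rows that cannot be placed are skipped with a log message."""
    hits: list[MarkerHit] = []
    for row in rows:
        if row.has_coordinates:
            hits.append(
                MarkerHit(
                    row.locus,
                    row.marker_name,
                    GenomicInterval(row.chrom, row.start, row.end),
                )
            )
        elif reference is not None and row.forward_primer and row.reverse_primer:
            hit = locate_primer_pair(
                row.forward_primer,
                row.reverse_primer,
                reference,
                locus=row.locus,
                marker_name=row.marker_name,
                max_span=max_span,
            )
            if hit is not None:
                hits.append(hit)
        else:
            logger.info("marker %s/%s: no coordinates and no reference; skipped",
                        row.locus, row.marker_name)
    return hits


def build_locus(hits: Sequence[MarkerHit]) -> LocusRegion:
    """Union span of one locus's marker hits (all on one chromosome)."""
    if not hits:
        raise ValueError("build_locus needs ≥1 marker hit")
    loci = {h.locus for h in hits}
    if len(loci) != 1:
        raise ValueError(f"hits span multiple loci: {sorted(loci)}")
    chroms = {h.interval.chrom for h in hits}
    if len(chroms) != 1:
        raise ValueError(
            f"locus {hits[0].locus}: marker hits on multiple chromosomes "
            f"{sorted(chroms)}"
        )
    chrom = chroms.pop()
    start = min(h.interval.start for h in hits)
    end = max(h.interval.end for h in hits)
    return LocusRegion(hits[0].locus, chrom, GenomicInterval(chrom, start, end))


def locus_breakdown(
    region: LocusRegion,
    genes: Sequence[GeneRecord],
    classes: Mapping[str, RgaClass],
    events: Sequence[GeneCnvEvent],
) -> dict[str, dict[str, int]]:
    """Per-class candidate and CNV-affected counts inside a locus region.

    An RGA is a candidate iff its interval overlaps the region by ≥1 bp;
    affected iff it additionally has ≥1 CNV event. The affected genes are
    tallied by cross-sample status (del / dup / both), so per-class tallies
    sum to the affected count.
    """
    status = gene_status(events)
    out: dict[str, dict[str, int]] = {}
    for gene in genes:
        cls = classes.get(gene.gene_id)
        if cls is None or not cls.is_rga:
            continue
        if overlap_bp(gene.interval, region.interval) < 1:
            continue
        d = out.setdefault(
            cls.label, {"candidates": 0, "affected": 0, "del": 0, "dup": 0, "both": 0}
        )
        d["candidates"] += 1
        st = status.get(gene.gene_id)
        if st is not None:
            d["affected"] += 1
            d[{"deletion": "del", "duplication": "dup", "both": "both"}[st]] += 1
    return out


def _format_candidates(breakdown: Mapping[str, Mapping[str, int]]) -> str:
    parts = [
        f"{label} {breakdown[label]['candidates']}"
        for label in _CLASS_ORDER
        if label in breakdown
    ]
    return ", ".join(parts)


def _format_affected(breakdown: Mapping[str, Mapping[str, int]]) -> str:
    parts = []
    for label in _CLASS_ORDER:
        d = breakdown.get(label)
        if not d or d["affected"] == 0:
            continue
        inner = [
            f"{d[k]} {k}" for k in ("del", "dup", "both") if d[k] > 0
        ]
        parts.append(f"{label} {d['affected']} ({', '.join(inner)})")
    return ", ".join(parts)


def qtl_table(
    regions: Sequence[LocusRegion],
    genes: Sequence[GeneRecord],
    classes: Mapping[str, RgaClass],
    events: Sequence[GeneCnvEvent],
) -> pd.DataFrame:
    """Per-locus summary rows: coordinates in Mbp, candidate and affected
    RGA breakdowns as display strings plus numeric totals."""
    rows = []
    for region in regions:
        b = locus_breakdown(region, genes, classes, events)
        rows.append(
            {
                "locus": region.locus,
                "chrom": region.chrom,
                "start_mbp": round(region.interval.start / 1e6, 2),
                "end_mbp": round(region.interval.end / 1e6, 2),
                "length_mbp": region.length_mbp,
                "rga_candidates": _format_candidates(b),
                "n_candidates": sum(d["candidates"] for d in b.values()),
                "rga_affected": _format_affected(b),
                "n_affected": sum(d["affected"] for d in b.values()),
            }
        )
    return pd.DataFrame(rows).sort_values("locus", kind="mergesort").reset_index(
        drop=True
    )
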