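"""Readers and writers for every external format the pipeline touches.

Formats handled: CNVnator 9-column call text, GFF3 gene annotation, FASTA
(for assembly-gap detection), BED gap tracks, and the TSV dialects used for
protein-domain profiles, genotype matrices, marker/primer tables and report
output. All coordinates are converted to the package-internal 0-based
half-open convention on read (GFF3 and CNVnator are 1-based inclusive; BED
passes through).
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval

__all__ = [
    "CnvCall",
    "GeneRecord",
    "DomainProfile",
    "GapTrack",
    "MarkerRow",
    "GenotypeMatrix",
    "DOMAIN_VOCABULARY",
    "ParseError",
    "read_cnvnator",
    "write_cnvnator",
    "read_gff3_genes",
    "write_gff3_genes",
    "gaps_from_fasta",
    "read_bed_gaps",
    "write_bed_gaps",
    "read_domain_table",
    "write_domain_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_marker_table",
    "write_marker_table",
    "write_tsv_report",
]

#: Controlled vocabulary for protein-domain labels driving RGA classification.
DOMAIN_VOCABULARY = frozenset(
    {"TIR", "NB-ARC", "LRR", "CC", "RPW8", "KINASE", "TM", "LysM", "SP", "UNKNOWN"}
)

CNV_TYPES = ("deletion", "duplication")


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class CnvCall:
    """One read-depth CNV call for one sample.

    ``e_values`` holds the four significance columns of the CNVnator output
    dialect; the filtered ``e_value`` is the first of them. ``q0`` is the
    fraction of zero-mapping-quality reads in the call (−1 = no reads,
    treated as missing by the quality filter).
    """

    call_id: str
    sample: str
    interval: GenomicInterval
    cnv_type: str
    normalized_rd: float
    e_values: tuple[float, float, float, float]
    q0: float

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}: {self.cnv_type}")
        if not (0.0 <= self.q0 <= 1.0 or self.q0 == -1.0):
            raise ValueError(f"q0 must be in [0,1] or the -1 missing flag: {self.q0}")

    @property
    def e_value(self) -> float:
        return self.e_values[0]

    @property
    def size_bp(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its interval and per-chromosome rank.

    ``chrom_rank`` is the 0-based position of the gene when all annotated
    genes on its chromosome are sorted by start coordinate; it is the
    distance unit for ±N-gene physical clustering.
    """

    gene_id: str
    interval: GenomicInterval
    chrom_rank: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class DomainProfile:
    """The set of protein domains detected on one gene product."""

    gene_id: str
    domains: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.domains - DOMAIN_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown domain label(s) for {self.gene_id}: {sorted(unknown)}"
            )


class GapTrack:
    """Assembly N-gap intervals, merged and sorted per chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append(iv)
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            merged: list[GenomicInterval] = []
            for iv in ivs:
                if merged and iv.start <= merged[-1].end:
                    if iv.end > merged[-1].end:
                        merged[-1] = GenomicInterval(chrom, merged[-1].start, iv.end)
                else:
                    merged.append(iv)
            self._by_chrom[chrom] = merged

    @property
    def intervals(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for chrom in sorted(self._by_chrom):
            out.extend(self._by_chrom[chrom])
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """Gap intervals on ``iv``'s chromosome that overlap it by ≥1 bp."""
        gaps = self._by_chrom.get(iv.chrom, [])
        starts = [g.start for g in gaps]
        i = bisect_left(starts, iv.end)
        out = []
        for g in gaps[:i]:
            if g.end > iv.start:
                out.append(g)
        return out


@dataclass(frozen=True)
class MarkerRow:
    """One row of the marker table: a locus-linked marker.

    A marker is located either by its primer pair (exact-match placement on
    the reference) or by precomputed coordinates; when both are present the
    coordinates take precedence.
    """

    locus: str
    marker_name: str
    forward_primer: str | None = None
    reverse_primer: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None


# ---------------------------------------------------------------------------
# CNVnator call files
# ---------------------------------------------------------------------------

_COORD_RE = re.compile(r"^(\S+):(\d+)-(\d+)$")


def read_cnvnator(path: str | Path, sample_name: str) -> list[CnvCall]:
    """Parse a CNVnator text output file into calls for one sample.

    Dialect: whitespace-separated columns — type, chrom:start-end (1-based
    inclusive), size, normalized read depth, four e-values, q0. The filtered
    e-value is column 5 (the first e-value). Type tokens other than
    ``deletion``/``duplication`` are rejected.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{lineno}: expected ≥9 whitespace-separated fields, "
                    f"got {len(fields)}"
                )
            cnv_type = fields[0]
            if cnv_type not in CNV_TYPES:
                raise ParseError(
                    f"{path}:{lineno}: unsupported CNV type token {cnv_type!r}"
                )
            m = _COORD_RE.match(fields[1])
            if m is None:
                raise ParseError(
                    f"{path}:{lineno}: malformed coordinate token {fields[1]!r}"
                )
            chrom, start1, end1 = m.group(1), int(m.group(2)), int(m.group(3))
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start in {fields[1]!r}")
            try:
                normalized_rd = float(fields[3])
                e_values = tuple(float(x) for x in fields[4:8])
                q0 = float(fields[8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            interval = GenomicInterval(chrom, start1 - 1, end1)
            calls.append(
                CnvCall(
                    call_id=f"{sample_name}:{lineno}",
                    sample=sample_name,
                    interval=interval,
                    cnv_type=cnv_type,
                    normalized_rd=normalized_rd,
                    e_values=e_values,  # type: ignore[arg-type]
                    q0=q0,
                )
            )
    return calls


def write_cnvnator(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Write calls in the CNVnator text dialect (inverse of ``read_cnvnator``)."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            evs = " ".join(repr(e) for e in c.e_values)
            fh.write(
                f"{c.cnv_type}\t{iv.chrom}:{iv.start + 1}-{iv.end}\t{iv.length}\t"
                f"{repr(c.normalized_rd)}\t{evs}\t{repr(c.q0)}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[GeneRecord]:
    """Read ``gene`` features from a GFF3 file and assign per-chromosome ranks.

    Only features of type ``gene`` are retained; other feature types are
    silently skipped. Each gene must carry an ``ID`` attribute; duplicate IDs
    are an error. ``chrom_rank`` is assigned by sorting genes within each
    chromosome on (start, end, gene_id).
    """
    raw: list[tuple[str, int, int, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            if fields[2] != "gene":
                continue
            chrom, start1, end1 = fields[0], int(fields[3]), int(fields[4])
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            raw.append((chrom, start1 - 1, end1, gene_id))

    genes: list[GeneRecord] = []
    by_chrom: dict[str, list[tuple[str, int, int, str]]] = {}
    for rec in raw:
        by_chrom.setdefault(rec[0], []).append(rec)
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom], key=lambda r: (r[1], r[2], r[3]))
        for rank, (c, s, e, gid) in enumerate(rows):
            genes.append(GeneRecord(gid, GenomicInterval(c, s, e), rank))
    return genes


def write_gff3_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.gene_id)):
            iv = g.interval
            fh.write(
                f"{iv.chrom}\trgacnv\tgene\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Assembly gaps
# ---------------------------------------------------------------------------

_N_RUN_RE = re.compile(r"[Nn]+")


def gaps_from_fasta(path: str | Path, min_run: int = 1) -> GapTrack:
    """Detect maximal runs of N/n of length ≥ ``min_run`` in a FASTA file."""
    intervals: list[GenomicInterval] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(record.seq)
        for m in _N_RUN_RE.finditer(seq):
            if m.end() - m.start() >= min_run:
                intervals.append(GenomicInterval(record.id, m.start(), m.end()))
    if n_records == 0:
        raise ParseError(f"{path}: no FASTA records found")
    return GapTrack(intervals)


def read_bed_gaps(path: str | Path) -> GapTrack:
    """Read a 0-based half-open BED gap track (first three columns used)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected ≥3 BED columns")
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return GapTrack(intervals)


def write_bed_gaps(track: GapTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Domain profiles
# ---------------------------------------------------------------------------

def read_domain_table(path: str | Path) -> list[DomainProfile]:
    """Read the per-gene domain TSV (columns: gene_id, domains).

    ``domains`` is a comma-separated list drawn from the controlled
    vocabulary; the empty string denotes a gene with no detected domain.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "domains"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: domain table must have columns {sorted(required)}")
    profiles = []
    for _, row in df.iterrows():
        labels = frozenset(d for d in row["domains"].split(",") if d)
        try:
            profiles.append(DomainProfile(row["gene_id"], labels))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return profiles


def write_domain_table(profiles: Sequence[DomainProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdomains\n")
        for p in sorted(profiles, key=lambda p: p.gene_id):
            fh.write(f"{p.gene_id}\t{','.join(sorted(p.domains))}\n")


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic genotypes: rows = sites, columns = samples.

    Codes are allele counts 0/1/2; −1 marks a missing call (written as
    ``"."`` on disk). Pairwise distances require ≥1 co-observed site per
    sample pair.
    """

    samples: list[str]
    site_ids: list[str]
    data: np.ndarray = field(repr=False)  # shape (n_sites, n_samples), int8

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("genotype matrix needs ≥2 samples")
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.site_ids), len(self.samples)):
            raise ValueError("genotype data shape mismatch")
        bad = ~np.isin(self.data, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or -1 (missing)")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV: header ``site <sample>...``, cells 0/1/2/``.``."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "site":
            raise ParseError(f"{path}: header must be 'site' followed by ≥2 samples")
        samples = header[1:]
        site_ids = []
        rows = []
        for lineno, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: ragged row")
            site_ids.append(fields[0])
            row = []
            for cell in fields[1:]:
                if cell == ".":
                    row.append(-1)
                elif cell in ("0", "1", "2"):
                    row.append(int(cell))
                else:
                    raise ParseError(
                        f"{path}:{lineno}: invalid genotype code {cell!r}"
                    )
            rows.append(row)
    return GenotypeMatrix(samples, site_ids, np.array(rows, dtype=np.int8))


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(gm.samples) + "\n")
        for sid, row in zip(gm.site_ids, gm.data):
            cells = [("." if v < 0 else str(int(v))) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------

_PRIMER_RE = re.compile(r"^[ACGT]+$")

_MARKER_COLUMNS = [
    "locus", "marker_name", "forward_primer", "reverse_primer",
    "chrom", "start", "end",
]


def read_marker_table(path: str | Path) -> list[MarkerRow]:
    """Read the locus/marker TSV. Primer-only rows must carry valid primers;
    rows with chrom/start/end use those coordinates directly."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"locus", "marker_name"}.issubset(df.columns):
        raise ParseError(f"{path}: marker table must have locus and marker_name")
    rows: list[MarkerRow] = []
    for idx, row in df.iterrows():
        fwd = row.get("forward_primer", "") or None
        rev = row.get("reverse_primer", "") or None
        chrom = row.get("chrom", "") or None
        start = row.get("start", "")
        end = row.get("end", "")
        start_i = int(start) if start != "" else None
        end_i = int(end) if end != "" else None
        for primer in (fwd, rev):
            if primer is not None and not _PRIMER_RE.match(primer):
                raise ParseError(
                    f"{path}: row {idx + 2}: primer contains characters "
                    f"outside ACGT: {primer!r}"
                )
        if chrom is None and (fwd is None or rev is None):
            raise ParseError(
                f"{path}: row {idx + 2}: marker needs either a primer pair or "
                "explicit coordinates"
            )
        rows.append(
            MarkerRow(row["locus"], row["marker_name"], fwd, rev, chrom, start_i, end_i)
        )
    return rows


def write_marker_table(rows: Sequence[MarkerRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MARKER_COLUMNS) + "\n")
        for r in sorted(rows, key=lambda r: (r.locus, r.marker_name)):
            fh.write(
                "\t".join(
                    [
                        r.locus,
                        r.marker_name,
                        r.forward_primer or "",
                        r.reverse_primer or "",
                        r.chrom or "",
                        "" if r.start is None else str(r.start),
                        "" if r.end is None else str(r.end),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def write_tsv_report(
    df: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None
) -> None:
    """Write a report table with a deterministic column order and row sort."""
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
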