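"""Gene-level CNV events and cross-cultivar summary tables.

A filtered CNV call is associated with a gene when a single call covers at
least half of the gene's length (bedtools ``intersect -f 0.50`` applied per
call/gene pair — fragmented sub-threshold coverage does not qualify). Calls
of the same type in the same sample collapse to one event per (gene,
sample, type).

The summary functions reproduce the cross-cultivar report shapes: per-sample
event counts with deletion/duplication percentages and "both" counts, the
pairwise shared-RGA matrix, the sharing histogram over the number of
cultivars, per-chromosome and per-sub-genome distributions, size-bin
histograms and per-sample mean sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CnvCall, GeneRecord
from .intervals import overlap_bp, round_half_up, subgenome

__all__ = [
    "GeneCnvEvent",
    "percentage",
    "associate",
    "gene_status",
    "supporting_call_ids",
    "event_counts_per_sample",
    "shared_matrix",
    "sharing_histogram",
    "size_location_summaries",
    "SIZE_BIN_EDGES",
]

#: Size-bin boundaries (bp), closed-left/open-right; calls are ≥ 50 bp.
SIZE_BIN_EDGES = (50, 1000, 5000, 10000)
SIZE_BIN_LABELS = ("50-1000", "1000-5000", "5000-10000", ">=10000")


@dataclass(frozen=True)
class GeneCnvEvent:
    """One (gene, sample, CNV type) event with its supporting call ids."""

    gene_id: str
    sample: str
    cnv_type: str
    supporting_calls: tuple[str, ...]


def percentage(n: float, total: float, decimals: int = 2) -> float:
    """``100 * n / total`` rounded half-up; 0 when the denominator is 0."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * n / total, decimals)


def associate(
    calls: Sequence[CnvCall],
    genes: Sequence[GeneRecord],
    frac: float = 0.5,
) -> list[GeneCnvEvent]:
    """Associate filtered calls with genes covered ≥ ``frac`` by one call.

    Returns one event per (gene, sample, type), sorted deterministically,
    with all supporting call ids attached.
    """
    trees: dict[str, IntervalTree] = {}
    for i, call in enumerate(calls):
        iv = call.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    events: dict[tuple[str, str, str], list[str]] = {}
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        giv = gene.interval
        for node in sorted(tree.overlap(giv.start, giv.end), key=lambda n: n.data):
            call = calls[node.data]
            if overlap_bp(giv, call.interval) / giv.length >= frac:
                key = (gene.gene_id, call.sample, call.cnv_type)
                events.setdefault(key, []).append(call.call_id)
    return [
        GeneCnvEvent(gid, sample, ctype, tuple(ids))
        for (gid, sample, ctype), ids in sorted(events.items())
    ]


def gene_status(events: Sequence[GeneCnvEvent]) -> dict[str, str]:
    """Partition genes with ≥1 event into deletion / duplication / both.

    A gene is "both" when it has a deletion event in at least one sample and
    a duplication event in at least one sample (possibly the same sample).
    """
    types: dict[str, set[str]] = {}
    for ev in events:
        types.setdefault(ev.gene_id, set()).add(ev.cnv_type)
    return {
        gid: ("both" if len(ts) == 2 else next(iter(ts)))
        for gid, ts in types.items()
    }


def supporting_call_ids(events: Sequence[GeneCnvEvent]) -> set[str]:
    """Ids of calls that support at least one gene event (counted calls)."""
    return {cid for ev in events for cid in ev.supporting_calls}


def _call_to_genes(events: Sequence[GeneCnvEvent]) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for ev in events:
        for cid in ev.supporting_calls:
            mapping.setdefault(cid, set()).add(ev.gene_id)
    return mapping


def counted_calls(
    events: Sequence[GeneCnvEvent], calls: Sequence[CnvCall]
) -> list[CnvCall]:
    """The calls counted in the per-sample event table: each call once,
    provided it supports ≥1 gene event (a call spanning two genes counts
    once)."""
    ids = supporting_call_ids(events)
    return [c for c in calls if c.call_id in ids]


def event_counts_per_sample(
    events: Sequence[GeneCnvEvent],
    calls: Sequence[CnvCall],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample deletion/duplication event counts and "both" counts.

    An event here is a counted call (a filtered call supporting ≥1 gene
    association). The "both" column counts the sample's events whose
    supported gene has cross-sample status both. A grand-total row is
    appended; percentages are of each sample's total.
    """
    status = gene_status(events)
    both_genes = {g for g, s in status.items() if s == "both"}
    call_genes = _call_to_genes(events)
    counted = counted_calls(events, calls)
    if samples is None:
        samples = sorted({c.sample for c in calls})

    rows = []
    tot_del = tot_dup = tot_both = 0
    for sample in samples:
        mine = [c for c in counted if c.sample == sample]
        n_del = sum(1 for c in mine if c.cnv_type == "deletion")
        n_dup = sum(1 for c in mine if c.cnv_type == "duplication")
        n_both = sum(1 for c in mine if call_genes[c.call_id] & both_genes)
        total = n_del + n_dup
        rows.append(
            {
                "sample": sample,
                "deletion": n_del,
                "deletion_pct": percentage(n_del, total),
                "duplication": n_dup,
                "duplication_pct": percentage(n_dup, total),
                "total": total,
                "both": n_both,
                "both_pct": percentage(n_both, total),
            }
        )
        tot_del += n_del
        tot_dup += n_dup
        tot_both += n_both
    grand = tot_del + tot_dup
    rows.append(
        {
            "sample": "Total",
            "deletion": tot_del,
            "deletion_pct": percentage(tot_del, grand),
            "duplication": tot_dup,
            "duplication_pct": percentage(tot_dup, grand),
            "total": grand,
            "both": tot_both,
            "both_pct": percentage(tot_both, grand),
        }
    )
    return pd.DataFrame(rows)


def shared_matrix(
    events: Sequence[GeneCnvEvent], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise counts of genes with the same CNV type in both samples.

    Cell (i, j) for i ≠ j counts genes with ≥1 event of identical type in
    both sample i and sample j; a gene deleted in one and duplicated in the
    other does not count. The diagonal is left blank (NaN).
    """
    if samples is None:
        samples = sorted({ev.sample for ev in events})
    per_sample: dict[str, set[tuple[str, str]]] = {s: set() for s in samples}
    for ev in events:
        if ev.sample in per_sample:
            per_sample[ev.sample].add((ev.gene_id, ev.cnv_type))
    mat = pd.DataFrame(np.nan, index=list(samples), columns=list(samples))
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            shared = {g for g, _ in per_sample[si] & per_sample[sj]}
            mat.loc[si, sj] = mat.loc[sj, si] = len(shared)
    return mat


def sharing_histogram(
    events: Sequence[GeneCnvEvent], n_samples: int
) -> pd.DataFrame:
    """How many genes carry CNV in exactly k of the samples, k = 1..n.

    Percentages are of the total number of genes with ≥1 event.
    """
    samples_per_gene: dict[str, set[str]] = {}
    for ev in events:
        samples_per_gene.setdefault(ev.gene_id, set()).add(ev.sample)
    total = len(samples_per_gene)
    counts = {k: 0 for k in range(1, n_samples + 1)}
    for ss in samples_per_gene.values():
        counts[len(ss)] += 1
    return pd.DataFrame(
        {
            "n_cultivars": list(counts.keys()),
            "rgas": list(counts.values()),
            "pct": [percentage(v, total) for v in counts.values()],
        }
    )


def size_location_summaries(calls: Sequence[CnvCall]) -> dict[str, object]:
    """Genomic distribution and size summaries over the counted calls.

    Returns per-chromosome and per-sub-genome deletion/duplication counts,
    the size-bin histogram (bins [50,1000), [1000,5000), [5000,10000),
    [10000,∞) bp), per-sample mean sizes in kb (2 d.p.), the overall mean
    size and the fraction of calls larger than 1 kb. Calls on chromosomes
    outside the A/C sub-genomes are excluded from sub-genome tallies only.
    """
    df = pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "chrom": [c.interval.chrom for c in calls],
            "subgenome": [subgenome(c.interval.chrom) for c in calls],
            "cnv_type": [c.cnv_type for c in calls],
            "size_bp": [c.size_bp for c in calls],
        }
    )

    def counts_by(key: str, frame: pd.DataFrame) -> pd.DataFrame:
        out = (
            frame.groupby([key, "cnv_type"]).size().unstack(fill_value=0)
            .reindex(columns=["deletion", "duplication"], fill_value=0)
            .reset_index()
        )
        out.columns.name = None
        out["total"] = out["deletion"] + out["duplication"]
        return out.sort_values(key, kind="mergesort").reset_index(drop=True)

    by_chrom = counts_by("chrom", df)
    by_sub = counts_by("subgenome", df[df["subgenome"].notna()])

    edges = list(SIZE_BIN_EDGES) + [np.inf]
    binned = pd.cut(
        df["size_bp"], bins=edges, right=False, labels=SIZE_BIN_LABELS
    )
    size_bins = (
        binned.value_counts().reindex(SIZE_BIN_LABELS, fill_value=0)
        .rename_axis("size_bin").reset_index(name="count")
    )
    n = len(df)
    size_bins["pct"] = [percentage(v, n) for v in size_bins["count"]]

    mean_kb = (
        df.groupby("sample")["size_bp"].mean().apply(lambda v: round_half_up(v / 1e3))
        .rename("mean_size_kb").reset_index()
    )
    mean_kb_by_type = (
        df.groupby(["sample", "cnv_type"])["size_bp"].mean()
        .apply(lambda v: round_half_up(v / 1e3)).unstack()
    )

    return {
        "by_chromosome": by_chrom,
        "by_subgenome": by_sub,
        "size_bins": size_bins,
        "mean_size_kb_per_sample": mean_kb,
        "mean_size_kb_per_sample_type": mean_kb_by_type,
        "mean_size_kb": round_half_up(df["size_bp"].mean() / 1e3) if n else 0.0,
        "pct_gt_1kb": percentage(int((df["size_bp"] > 1000).sum()), n),
        "total_size_mbp": round_half_up(df["size_bp"].sum() / 1e6) if n else 0.0,
    }
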