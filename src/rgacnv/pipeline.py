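"""End-to-end orchestration: from a bundle of input files to all reports.

Stages, in order: read per-sample CNV calls → quality filter → gap filter →
classify RGAs from domain profiles → physical clustering → gene/CNV
association over the RGAs → cross-cultivar summaries → marker-anchored
locus breakdowns → genotype distances and the NJ sample tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import cnv_genes, filtering, io, loci, phylo, rga

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    samples: list[str]
    genes: list[io.GeneRecord]
    classes: dict[str, rga.RgaClass]
    rga_ids: set[str]
    clusters: list[rga.ClusterAssignment]
    singletons: set[str]
    calls_raw: list[io.CnvCall]
    calls_kept: list[io.CnvCall]
    removed_quality: list[tuple[io.CnvCall, str]]
    removed_gap: list[tuple[io.CnvCall, str]]
    events: list[cnv_genes.GeneCnvEvent]
    gene_status: dict[str, str]
    event_table: pd.DataFrame
    shared: pd.DataFrame
    sharing: pd.DataFrame
    summaries: dict[str, object]
    locus_regions: list[loci.LocusRegion] = field(default_factory=list)
    qtl: pd.DataFrame | None = None
    tree: object | None = None
    distance_matrix: pd.DataFrame | None = None

    @property
    def counted_calls(self) -> list[io.CnvCall]:
        return cnv_genes.counted_calls(self.events, self.calls_kept)


def run_pipeline(
    call_files: Mapping[str, str | Path],
    gff3_path: str | Path,
    domains_path: str | Path,
    gaps: io.GapTrack | None = None,
    marker_rows: Sequence[io.MarkerRow] | None = None,
    reference: Mapping[str, str] | None = None,
    genotypes_path: str | Path | None = None,
    filter_cfg: filtering.FilterConfig | None = None,
    assoc_frac: float = 0.5,
    cluster_window: int = 10,
) -> PipelineResult:
    """Run every pipeline stage for which inputs were provided."""
    filter_cfg = filter_cfg or filtering.FilterConfig()
    samples = sorted(call_files)

    calls_raw: list[io.CnvCall] = []
    for sample in samples:
        calls_raw.extend(io.read_cnvnator(call_files[sample], sample))

    kept, removed_quality = filtering.quality_filter(calls_raw, filter_cfg)
    removed_gap: list[tuple[io.CnvCall, str]] = []
    if gaps is not None:
        kept, removed_gap = filtering.gap_filter(kept, gaps, filter_cfg)

    genes = io.read_gff3_genes(gff3_path)
    profiles = io.read_domain_table(domains_path)
    classes = {p.gene_id: rga.classify_rga(p) for p in profiles}
    rga_ids = {gid for gid, c in classes.items() if c.is_rga}
    clusters, singletons = rga.build_clusters(genes, rga_ids, window=cluster_window)

    rga_genes = [g for g in genes if g.gene_id in rga_ids]
    events = cnv_genes.associate(kept, rga_genes, frac=assoc_frac)
    status = cnv_genes.gene_status(events)
    event_table = cnv_genes.event_counts_per_sample(events, kept, samples=samples)
    shared = cnv_genes.shared_matrix(events, samples=samples)
    sharing = cnv_genes.sharing_histogram(events, n_samples=len(samples))
    summaries = cnv_genes.size_location_summaries(
        cnv_genes.counted_calls(events, kept)
    )

    result = PipelineResult(
        samples=samples,
        genes=genes,
        classes=classes,
        rga_ids=rga_ids,
        clusters=clusters,
        singletons=singletons,
        calls_raw=calls_raw,
        calls_kept=kept,
        removed_quality=removed_quality,
        removed_gap=removed_gap,
        events=events,
        gene_status=status,
        event_table=event_table,
        shared=shared,
        sharing=sharing,
        summaries=summaries,
    )

    if marker_rows:
        hits = loci.locate_markers(marker_rows, reference)
        by_locus: dict[str, list[loci.MarkerHit]] = {}
        for h in hits:
            by_locus.setdefault(h.locus, []).append(h)
        regions = [loci.build_locus(hs) for hs in by_locus.values()]
        regions.sort(key=lambda r: r.locus)
        result.locus_regions = regions
        result.qtl = loci.qtl_table(regions, rga_genes, classes, events)

    if genotypes_path is not None:
        gm = io.read_genotype_matrix(genotypes_path)
        D, names = phylo.genotype_distance(gm)
        result.distance_matrix = pd.DataFrame(D, index=names, columns=names)
        result.tree = phylo.neighbor_joining(D, names)

    return result
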