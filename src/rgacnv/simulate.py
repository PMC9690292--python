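"""Synthetic study bundles with planted truth.

The study's sequencing data are not deposited, so this module generates
every input the pipeline consumes at desk scale: a multi-chromosome A/C
sub-genome reference with planted N-gaps, a gene annotation of which a
configurable fraction are RGAs with by-construction domain profiles and a
planted cluster/singleton structure, per-sample CNVnator-style call files
(planted calls covering planted genes, plus noise calls that fail the
quality filter and gap-artifact calls removed by the gap filter), a marker
table whose primers are copied verbatim from the reference, and a biallelic
genotype matrix evolved along a known tree.

Everything is driven by one integer seed; the same seed yields a
byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .intervals import GenomicInterval
from .io import (
    CnvCall,
    GapTrack,
    GeneRecord,
    GenotypeMatrix,
    DomainProfile,
    MarkerRow,
    write_bed_gaps,
    write_cnvnator,
    write_domain_table,
    write_genotype_matrix,
    write_gff3_genes,
    write_marker_table,
)
from .phylo import read_newick

__all__ = [
    "PlantedEvent",
    "SimConfig",
    "TruthSet",
    "SimBundle",
    "simulate",
    "default_paper_like_config",
    "evolve_genotypes",
    "random_tree",
    "CLASS_DOMAINS",
    "DEFAULT_SAMPLES",
    "DEFAULT_TREE",
]

#: Eight winter-type cultivars used as default sample names.
DEFAULT_SAMPLES = (
    "Ascona",
    "English_Giant",
    "Hansen_x_Gaspard",
    "Milena",
    "Pacific",
    "Pirola",
    "Tina",
    "Wilhelmsburger",
)

#: Default generating tree over the eight cultivars (branch lengths are
#: expected substitutions per site).
DEFAULT_TREE = (
    "((Ascona:0.020,Pirola:0.028):0.012,"
    "((Milena:0.022,Pacific:0.018):0.015,"
    "(English_Giant:0.030,(Hansen_x_Gaspard:0.024,"
    "(Tina:0.010,Wilhelmsburger:0.012):0.020):0.012):0.010):0.008);"
)

#: Minimal domain set realising each RGA class (inverse of the classifier).
CLASS_DOMAINS: dict[str, frozenset[str]] = {
    "NBS": frozenset({"NB-ARC"}),
    "TNL": frozenset({"TIR", "NB-ARC", "LRR"}),
    "TN": frozenset({"TIR", "NB-ARC"}),
    "CNL": frozenset({"CC", "NB-ARC", "LRR"}),
    "CN": frozenset({"CC", "NB-ARC"}),
    "NL": frozenset({"NB-ARC", "LRR"}),
    "TX": frozenset({"TIR", "UNKNOWN"}),
    "OTHER": frozenset({"CC", "NB-ARC", "LRR", "RPW8"}),
    "RLK": frozenset({"LRR", "TM", "KINASE"}),
    "RLP": frozenset({"LRR", "TM"}),
}

#: Class mix weighted toward RLK, echoing the observed RGA composition
#: (RLKs dominate, then RLPs and NL/TNL among the NLRs).
DEFAULT_CLASS_MIX: dict[str, float] = {
    "RLK": 0.55,
    "RLP": 0.15,
    "NL": 0.08,
    "TNL": 0.08,
    "CNL": 0.05,
    "NBS": 0.03,
    "TN": 0.02,
    "CN": 0.02,
    "TX": 0.01,
    "OTHER": 0.01,
}

_NON_RGA_DOMAINS = (
    frozenset(),
    frozenset({"UNKNOWN"}),
    frozenset({"KINASE"}),
    frozenset({"TM"}),
    frozenset({"SP"}),
    frozenset({"LRR"}),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedEvent:
    gene_id: str
    sample: str
    cnv_type: str
    coverage: float = 1.0


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults emulate the study design at desk scale: 8 cultivars, 19
    chromosomes (10 A + 9 C), 500 genes of which ~30% are RGAs in a mix
    dominated by RLKs, per-sample planted events with a deletion bias, and
    noise/gap-artifact calls engineered to exercise both filters including
    their inclusive boundaries.
    """

    seed: int = 0
    n_chroms_A: int = 10
    n_chroms_C: int = 9
    chrom_len: int | None = None  # None = auto-size to fit the genes
    n_genes: int = 500
    rga_fraction: float = 0.1
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_samples: int = 8
    sample_names: tuple[str, ...] | None = None
    planted_events: list[PlantedEvent] | None = None  # None = draw per sample
    events_per_sample: int = 12
    deletion_prob: float = 0.62
    noise_calls: int = 80
    gap_artifact_calls: int = 16
    gap_density: float = 20.0  # gaps per Mbp of desk-scale chromosome
    n_sites: int = 2000
    generating_tree: str | None = DEFAULT_TREE
    n_loci: int = 2
    missing_rate: float = 0.01
    cluster_window: int = 10

    def resolved_samples(self) -> tuple[str, ...]:
        if self.sample_names is not None:
            if len(self.sample_names) != self.n_samples:
                raise ValueError("sample_names length must equal n_samples")
            return tuple(self.sample_names)
        if self.n_samples == len(DEFAULT_SAMPLES):
            return DEFAULT_SAMPLES
        return tuple(f"S{i + 1}" for i in range(self.n_samples))


@dataclass
class TruthSet:
    """Planted ground truth, consistent with the emitted files."""

    events: list[PlantedEvent]
    gaps: list[GenomicInterval]
    markers: dict[str, GenomicInterval]
    tree_newick: str
    clusters: list[tuple[str, ...]]
    singletons: set[str]
    classes: dict[str, str]  # gene_id -> planted class label (RGAs only)
    noise_per_sample: dict[str, int]
    gap_artifacts_per_sample: dict[str, int]

    @property
    def rga_ids(self) -> set[str]:
        return set(self.classes)


@dataclass
class SimBundle:
    """Paths of an emitted bundle."""

    out_dir: Path
    reference_fasta: Path
    genes_gff3: Path
    domains_tsv: Path
    gaps_bed: Path
    call_files: dict[str, Path]
    markers_tsv: Path
    genotypes_tsv: Path


def default_paper_like_config(seed: int = 0) -> SimConfig:
    """The study-shaped default configuration (8 cultivars, 10+9 chromosomes)."""
    return SimConfig(seed=seed)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _apportion(weights: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items across weighted labels."""
    total = sum(weights.values())
    quotas = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n - sum(counts.values())
    order = sorted(weights, key=lambda k: (counts[k] - quotas[k], k))
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def random_tree(names: Sequence[str], rng: np.random.Generator) -> str:
    """A random bifurcating newick over ``names`` via successive joins."""
    nodes = [f"{nm}:{rng.uniform(0.01, 0.05):.4f}" for nm in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        joined = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.01, 0.05):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    return f"({nodes[0]},{nodes[1]});"


def evolve_genotypes(
    tree_newick: str,
    samples: Sequence[str],
    n_sites: int,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Evolve biallelic genotypes along a tree.

    Each branch of length *b* toggles ``Poisson(b · n_sites)`` uniformly
    chosen sites between the homozygous states 0 and 2, so the expected
    genotype distance between two leaves is close to their path length.
    Missing calls are sprinkled at ``missing_rate``.
    """
    tree = read_newick(tree_newick)
    leaf_names = {t.name for t in tree.get_terminals()}
    if leaf_names != set(samples):
        raise ValueError("tree leaves must match the sample names")

    leaf_geno: dict[str, np.ndarray] = {}

    def walk(clade, genotype: np.ndarray) -> None:
        bl = clade.branch_length or 0.0
        g = genotype
        if bl > 0:
            k = min(int(rng.poisson(bl * n_sites)), n_sites)
            if k:
                sites = rng.choice(n_sites, size=k, replace=False)
                g = genotype.copy()
                g[sites] = 2 - g[sites]
        if clade.is_terminal():
            leaf_geno[clade.name] = g
        else:
            for child in clade.clades:
                walk(child, g)

    walk(tree.root, np.zeros(n_sites, dtype=np.int8))

    data = np.stack([leaf_geno[s] for s in samples], axis=1)
    if missing_rate > 0:
        mask = rng.random(data.shape) < missing_rate
        data = data.copy()
        data[mask] = -1
    # keep biallelic (polymorphic) sites only
    observed = np.ma.masked_array(data, data < 0)
    poly = (observed.max(axis=1) != observed.min(axis=1)).filled(False)
    data = data[poly]
    site_ids = [f"snp{i + 1}" for i in range(data.shape[0])]
    return GenotypeMatrix(list(samples), site_ids, data)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig, out_dir: str | Path) -> tuple[SimBundle, TruthSet]:
    """Generate a full input bundle plus its planted truth.

    Raises if the configured genes cannot be packed into ``chrom_len``.
    """
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = cfg.resolved_samples()

    chrom_names = [f"chrA{i + 1:02d}" for i in range(cfg.n_chroms_A)] + [
        f"chrC{i + 1:02d}" for i in range(cfg.n_chroms_C)
    ]
    n_chroms = len(chrom_names)
    if n_chroms == 0:
        raise ValueError("need at least one chromosome")

    # --- gene placement -----------------------------------------------------
    per_chrom = [cfg.n_genes // n_chroms] * n_chroms
    for i in range(cfg.n_genes % n_chroms):
        per_chrom[i] += 1

    genes: list[GeneRecord] = []
    chrom_lens: dict[str, int] = {}
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    gene_counter = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        pos = 2000
        chrom_genes: list[GeneRecord] = []
        for rank in range(n_here):
            spacing = int(rng.integers(500, 5001))
            length = int(rng.integers(1000, 5001))
            start = pos + spacing
            end = start + length
            gene_counter += 1
            gid = f"BnaG{gene_counter:05d}"
            chrom_genes.append(GeneRecord(gid, GenomicInterval(chrom, start, end), rank))
            pos = end
        needed = pos + 2000
        if cfg.chrom_len is not None:
            if needed > cfg.chrom_len:
                raise ValueError(
                    f"infeasible packing: {n_here} genes need {needed} bp on "
                    f"{chrom} but chrom_len is {cfg.chrom_len}"
                )
            chrom_lens[chrom] = cfg.chrom_len
        else:
            chrom_lens[chrom] = needed
        genes.extend(chrom_genes)
        genes_by_chrom[chrom] = chrom_genes

    # --- RGA selection with planted cluster structure -----------------------
    n_rga_target = int(round(cfg.n_genes * cfg.rga_fraction))
    window = cfg.cluster_window
    truth_clusters: list[tuple[str, ...]] = []
    truth_singletons: set[str] = set()
    rga_ids: list[str] = []
    for chrom in chrom_names:
        chrom_genes = genes_by_chrom[chrom]
        n_here = len(chrom_genes)
        rank = int(rng.integers(0, 3))
        while rank < n_here and len(rga_ids) < n_rga_target:
            # ~40% singleton groups; clustered RGAs sit 1-3 ranks apart
            group_size = int(rng.choice([1, 1, 1, 1, 1, 1, 1, 2, 2, 3, 4]))
            members: list[str] = []
            r = rank
            while len(members) < group_size and r < n_here and len(rga_ids) < n_rga_target:
                members.append(chrom_genes[r].gene_id)
                rga_ids.append(chrom_genes[r].gene_id)
                r += int(rng.integers(1, 4))
            if len(members) >= 2:
                truth_clusters.append(tuple(members))
            elif members:
                truth_singletons.add(members[0])
            rank = r + window + int(rng.integers(1, 5))
        if len(rga_ids) >= n_rga_target:
            break

    # --- class assignment and domain profiles -------------------------------
    counts = _apportion(cfg.class_mix, len(rga_ids))
    labels: list[str] = []
    for label in DEFAULT_CLASS_MIX:  # stable label order
        labels.extend([label] * counts.get(label, 0))
    for label in counts:
        if label not in DEFAULT_CLASS_MIX:
            labels.extend([label] * counts[label])
    perm = rng.permutation(len(rga_ids))
    truth_classes = {rga_ids[i]: labels[perm[i]] for i in range(len(rga_ids))}

    profiles: list[DomainProfile] = []
    rga_set = set(rga_ids)
    for g in genes:
        if g.gene_id in rga_set:
            domains = CLASS_DOMAINS[truth_classes[g.gene_id]]
        else:
            domains = _NON_RGA_DOMAINS[int(rng.integers(0, len(_NON_RGA_DOMAINS)))]
        profiles.append(DomainProfile(g.gene_id, frozenset(domains)))

    # --- gaps in intergenic space -------------------------------------------
    truth_gaps: list[GenomicInterval] = []
    margin = 60
    for chrom in chrom_names:
        length = chrom_lens[chrom]
        n_gaps = int(round(cfg.gap_density * length / 1e6))
        if n_gaps == 0:
            continue
        chrom_genes = genes_by_chrom[chrom]
        slots = []
        prev_end = 0
        for g in chrom_genes:
            if g.interval.start - prev_end >= 2 * margin + 1600:
                slots.append((prev_end + margin, g.interval.start - margin))
            prev_end = g.interval.end
        if length - prev_end >= 2 * margin + 1600:
            slots.append((prev_end + margin, length - margin))
        if not slots:
            continue
        chosen = rng.choice(len(slots), size=min(n_gaps, len(slots)), replace=False)
        for idx in sorted(int(i) for i in chosen):
            lo, hi = slots[idx]
            gap_len = int(rng.integers(200, 1501))
            centre = (lo + hi) // 2
            gs = max(lo, centre - gap_len // 2)
            truth_gaps.append(GenomicInterval(chrom, gs, gs + gap_len))

    # --- reference sequence --------------------------------------------------
    seqs: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        arr = _BASES[rng.integers(0, 4, size=chrom_lens[chrom])]
        seqs[chrom] = arr
    for gap in truth_gaps:
        seqs[gap.chrom][gap.start:gap.end] = ord("N")
    seq_strings = {c: a.tobytes().decode("ascii") for c, a in seqs.items()}

    # --- planted events ------------------------------------------------------
    genes_by_id = {g.gene_id: g for g in genes}
    if cfg.planted_events is not None:
        planted = list(cfg.planted_events)
    else:
        planted = []
        n_ev = min(cfg.events_per_sample, len(rga_ids))
        for sample in samples:
            chosen = rng.choice(len(rga_ids), size=n_ev, replace=False)
            for idx in sorted(int(i) for i in chosen):
                cnv_type = (
                    "deletion" if rng.random() < cfg.deletion_prob else "duplication"
                )
                planted.append(PlantedEvent(rga_ids[idx], sample, cnv_type, 1.0))

    # --- per-sample call files ----------------------------------------------
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    calls_per_sample: dict[str, list[CnvCall]] = {s: [] for s in samples}

    def passing_eq(rng: np.random.Generator) -> tuple[float, float]:
        return float(rng.uniform(1e-12, 1e-3)), float(np.round(rng.uniform(0.0, 0.3), 4))

    for ev in planted:
        gene = genes_by_id[ev.gene_id]
        giv = gene.interval
        span = max(1, int(round(ev.coverage * giv.length)))
        iv = GenomicInterval(giv.chrom, giv.start, giv.start + span)
        e, q0 = passing_eq(rng)
        calls_per_sample[ev.sample].append(
            CnvCall("", ev.sample, iv, ev.cnv_type, 0.5 if ev.cnv_type == "deletion" else 1.6,
                    (e, 0.0, e, 0.0), q0)
        )

    noise_per_sample = {s: 0 for s in samples}
    for _ in range(cfg.noise_calls):
        sample = samples[int(rng.integers(0, len(samples)))]
        chrom = chrom_names[int(rng.integers(0, n_chroms))]
        clen = chrom_lens[chrom]
        length = int(rng.integers(100, 5001))
        start = int(rng.integers(0, max(1, clen - length)))
        mode = ("e", "q0", "both")[int(rng.integers(0, 3))]
        e_pass, q_pass = passing_eq(rng)
        e = float(rng.choice([0.05, 0.5])) if mode in ("e", "both") else e_pass
        q0 = float(rng.choice([0.5, 0.9])) if mode in ("q0", "both") else q_pass
        cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
        calls_per_sample[sample].append(
            CnvCall("", sample, GenomicInterval(chrom, start, start + length),
                    cnv_type, 1.0, (e, 0.0, e, 0.0), q0)
        )
        noise_per_sample[sample] += 1

    gap_artifacts_per_sample = {s: 0 for s in samples}
    if cfg.gap_artifact_calls and truth_gaps:
        for _ in range(cfg.gap_artifact_calls):
            sample = samples[int(rng.integers(0, len(samples)))]
            gap = truth_gaps[int(rng.integers(0, len(truth_gaps)))]
            e, q0 = passing_eq(rng)
            cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
            calls_per_sample[sample].append(
                CnvCall("", sample, gap, cnv_type, 0.1, (e, 0.0, e, 0.0), q0)
            )
            gap_artifacts_per_sample[sample] += 1

    call_files: dict[str, Path] = {}
    for sample in samples:
        calls = sorted(
            calls_per_sample[sample],
            key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type),
        )
        path = calls_dir / f"{sample}.cnvnator.txt"
        write_cnvnator(calls, path)
        call_files[sample] = path

    # --- markers -------------------------------------------------------------
    truth_markers: dict[str, GenomicInterval] = {}
    marker_rows: list[MarkerRow] = []
    rga_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.gene_id in rga_set:
            rga_by_chrom.setdefault(g.chrom, []).append(g)
    eligible = [
        c for c in chrom_names if len(genes_by_chrom[c]) >= 6 and rga_by_chrom.get(c)
    ]
    for li in range(cfg.n_loci):
        if not eligible:
            break
        chrom = eligible[int(rng.integers(0, len(eligible)))]
        chrom_genes = genes_by_chrom[chrom]
        # anchor the locus on an RGA so it holds candidate genes
        anchors = rga_by_chrom[chrom]
        anchor = anchors[int(rng.integers(0, len(anchors)))]
        i0 = max(0, anchor.chrom_rank - 1)
        i1 = min(len(chrom_genes) - 1, anchor.chrom_rank + int(rng.integers(1, 4)))
        locus_start = max(0, chrom_genes[i0].interval.start - 300)
        locus_end = min(chrom_lens[chrom], chrom_genes[i1].interval.end + 300)
        locus = f"SynRlm{li + 1}"
        if li % 2 == 1:
            # coordinate-anchored marker rows
            marker_rows.append(
                MarkerRow(locus, f"{locus}_m1", None, None, chrom, locus_start, locus_end)
            )
            truth_markers[locus] = GenomicInterval(chrom, locus_start, locus_end)
            continue
        seq = seq_strings[chrom]
        placed: list[tuple[int, int]] = []
        spans = []
        amp = int(rng.integers(900, 2000))
        spans.append((locus_start, locus_start + amp))
        amp2 = int(rng.integers(900, 2000))
        spans.append((locus_end - amp2, locus_end))
        for mi, (s, e) in enumerate(spans):
            attempts = 0
            while attempts < 30:
                fwd = seq[s:s + 20]
                rev = _revcomp(seq[e - 20:e])
                if (
                    "N" not in fwd and "N" not in rev
                    and _unique_in_genome(fwd, seq_strings)
                    and _unique_in_genome(_revcomp(rev), seq_strings)
                ):
                    marker_rows.append(
                        MarkerRow(locus, f"{locus}_m{mi + 1}", fwd, rev)
                    )
                    placed.append((s, e))
                    break
                s += 37
                e += 37
                attempts += 1
        if placed:
            truth_markers[locus] = GenomicInterval(
                chrom, min(s for s, _ in placed), max(e for _, e in placed)
            )

    # --- genotypes along the generating tree --------------------------------
    tree_newick = cfg.generating_tree or random_tree(samples, rng)
    gm = evolve_genotypes(tree_newick, samples, cfg.n_sites, rng, cfg.missing_rate)

    # --- write bundle --------------------------------------------------------
    records = [
        SeqRecord(Seq(seq_strings[c]), id=c, description="") for c in chrom_names
    ]
    ref_path = out / "reference.fasta"
    SeqIO.write(records, str(ref_path), "fasta")

    gff_path = out / "genes.gff3"
    write_gff3_genes(genes, gff_path)
    dom_path = out / "domains.tsv"
    write_domain_table(profiles, dom_path)
    gaps_path = out / "gaps.bed"
    write_bed_gaps(GapTrack(truth_gaps), gaps_path)
    markers_path = out / "markers.tsv"
    write_marker_table(marker_rows, markers_path)
    geno_path = out / "genotypes.tsv"
    write_genotype_matrix(gm, geno_path)

    truth = TruthSet(
        events=planted,
        gaps=truth_gaps,
        markers=truth_markers,
        tree_newick=tree_newick,
        clusters=truth_clusters,
        singletons=truth_singletons,
        classes=truth_classes,
        noise_per_sample=noise_per_sample,
        gap_artifacts_per_sample=gap_artifacts_per_sample,
    )
    _write_truth(out, truth)

    bundle = SimBundle(
        out_dir=out,
        reference_fasta=ref_path,
        genes_gff3=gff_path,
        domains_tsv=dom_path,
        gaps_bed=gaps_path,
        call_files=call_files,
        markers_tsv=markers_path,
        genotypes_tsv=geno_path,
    )
    return bundle, truth


def _unique_in_genome(needle: str, seqs: dict[str, str]) -> bool:
    count = 0
    rc = _revcomp(needle)
    for seq in seqs.values():
        count += seq.count(needle) + seq.count(rc)
        if count > 1:
            return False
    return count == 1


def _write_truth(out: Path, truth: TruthSet) -> None:
    with open(out / "truth_events.tsv", "w") as fh:
        fh.write("gene_id\tsample\tcnv_type\tcoverage\n")
        for ev in sorted(truth.events, key=lambda e: (e.gene_id, e.sample, e.cnv_type)):
            fh.write(f"{ev.gene_id}\t{ev.sample}\t{ev.cnv_type}\t{ev.coverage}\n")
    with open(out / "truth_gaps.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for iv in sorted(truth.gaps):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(out / "truth_markers.tsv", "w") as fh:
        fh.write("locus\tchrom\tstart\tend\n")
        for locus in sorted(truth.markers):
            iv = truth.markers[locus]
            fh.write(f"{locus}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(out / "truth_clusters.tsv", "w") as fh:
        fh.write("members\n")
        for cluster in truth.clusters:
            fh.write(",".join(cluster) + "\n")
        for s in sorted(truth.singletons):
            fh.write(s + "\n")
    with open(out / "truth_classes.tsv", "w") as fh:
        fh.write("gene_id\tclass\n")
        for gid in sorted(truth.classes):
            fh.write(f"{gid}\t{truth.classes[gid]}\n")
    with open(out / "truth_tree.nwk", "w") as fh:
        fh.write(truth.tree_newick.rstrip("\n") + "\n")
    with open(out / "truth_noise.tsv", "w") as fh:
        fh.write("sample\tnoise_calls\tgap_artifact_calls\n")
        for sample in sorted(truth.noise_per_sample):
            fh.write(
                f"{sample}\t{truth.noise_per_sample[sample]}\t"
                f"{truth.gap_artifacts_per_sample.get(sample, 0)}\n"
            )
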