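"""Resistance gene analogue (RGA) classification and physical clustering.

Genes are classified from their protein-domain profiles into the canonical
plant resistance-gene classes: the NLR family (NB-ARC-bearing proteins and
their truncated forms NBS/TNL/TN/CNL/CN/NL, TIR-only TX, and OTHER for NLR
architectures with extra domains) and the membrane receptor families RLK
(ectodomain + transmembrane + kinase) and RLP (ectodomain + transmembrane,
no kinase).

RGAs lying within a fixed number of annotated genes of each other on one
chromosome are chained into physical clusters; unclustered RGAs are
singletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import DOMAIN_VOCABULARY, DomainProfile, GeneRecord

__all__ = [
    "RgaClass",
    "ClusterAssignment",
    "NLR_LABELS",
    "RGA_LABELS",
    "classify_rga",
    "build_clusters",
]

#: NLR-family subclass labels.
NLR_LABELS = ("NBS", "TNL", "TN", "CNL", "CN", "NL", "TX", "OTHER")

#: All labels that mark a gene as an RGA.
RGA_LABELS = NLR_LABELS + ("RLK", "RLP")

_NLR_CORE = frozenset({"TIR", "CC", "NB-ARC", "LRR"})


@dataclass(frozen=True)
class RgaClass:
    """A subclass label plus the family it belongs to (NLR/RLK/RLP/NONE)."""

    label: str
    family: str

    def __post_init__(self) -> None:
        if self.label in NLR_LABELS:
            expected = "NLR"
        elif self.label in ("RLK", "RLP"):
            expected = self.label
        elif self.label == "NONE":
            expected = "NONE"
        else:
            raise ValueError(f"unknown RGA label {self.label!r}")
        if self.family != expected:
            raise ValueError(f"label {self.label} implies family {expected}")

    @property
    def is_rga(self) -> bool:
        return self.label != "NONE"


def _make(label: str) -> RgaClass:
    if label in NLR_LABELS:
        return RgaClass(label, "NLR")
    if label in ("RLK", "RLP"):
        return RgaClass(label, label)
    return RgaClass("NONE", "NONE")


def classify_rga(profile: DomainProfile) -> RgaClass:
    """Classify a gene from its domain profile.

    Decision ladder (first match wins):

    1. NB-ARC present with any domain outside {TIR, CC, NB-ARC, LRR}
       (e.g. RPW8) → OTHER.
    2. NB-ARC present: TIR+LRR → TNL; TIR alone → TN; CC+LRR → CNL;
       CC alone → CN; LRR without TIR/CC → NL; NB-ARC alone → NBS.
       (TIR takes precedence when both TIR and CC are present.)
    3. TIR present without NB-ARC → TX (truncated TIR protein, possibly
       with unknown domains).
    4. KINASE + TM + (LRR or LysM ectodomain) → RLK.
    5. TM + (LRR or LysM) without KINASE → RLP.
    6. Anything else → NONE.

    NLR evidence (NB-ARC) takes precedence over receptor-like patterns.
    """
    domains = profile.domains
    unknown = domains - DOMAIN_VOCABULARY
    if unknown:
        raise ValueError(f"unknown domain label(s): {sorted(unknown)}")

    if "NB-ARC" in domains:
        if domains - _NLR_CORE:
            return _make("OTHER")
        tir, cc, lrr = "TIR" in domains, "CC" in domains, "LRR" in domains
        if tir:
            return _make("TNL" if lrr else "TN")
        if cc:
            return _make("CNL" if lrr else "CN")
        if lrr:
            return _make("NL")
        return _make("NBS")
    if "TIR" in domains:
        return _make("TX")
    ecto = "LRR" in domains or "LysM" in domains
    if "TM" in domains and ecto:
        return _make("RLK" if "KINASE" in domains else "RLP")
    return _make("NONE")


@dataclass(frozen=True)
class ClusterAssignment:
    """A physical cluster of ≥2 RGAs on one chromosome.

    Members are ordered by chromosome rank; consecutive members differ by at
    most the clustering window in rank.
    """

    cluster_id: str
    chrom: str
    member_gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError("a cluster needs ≥2 members")


def build_clusters(
    genes: Sequence[GeneRecord],
    rga_ids: Iterable[str],
    window: int = 10,
) -> tuple[list[ClusterAssignment], set[str]]:
    """Chain RGAs within ±``window`` genes of each other into clusters.

    Distance is measured in gene-rank units counting all annotated genes,
    and chaining is transitive: if a–b and b–c are each within the window,
    a, b and c form one cluster. Maximal chains of size ≥2 become clusters
    (``<chrom>_c<ordinal>`` in coordinate order, 1-based); chains of size 1
    are singletons. A rank difference of exactly ``window`` still chains
    ("within").
    """
    rga_ids = set(rga_ids)
    by_id = {g.gene_id: g for g in genes}
    missing = rga_ids - by_id.keys()
    if missing:
        raise ValueError(f"RGA ids absent from gene list: {sorted(missing)[:5]}")

    by_chrom: dict[str, list[GeneRecord]] = {}
    for gid in rga_ids:
        g = by_id[gid]
        by_chrom.setdefault(g.chrom, []).append(g)

    clusters: list[ClusterAssignment] = []
    singletons: set[str] = set()
    for chrom in sorted(by_chrom):
        rgas = sorted(by_chrom[chrom], key=lambda g: g.chrom_rank)
        chains: list[list[GeneRecord]] = []
        for g in rgas:
            if chains and g.chrom_rank - chains[-1][-1].chrom_rank <= window:
                chains[-1].append(g)
            else:
                chains.append([g])
        ordinal = 0
        for chain in chains:  # already in coordinate order
            if len(chain) >= 2:
                ordinal += 1
                clusters.append(
                    ClusterAssignment(
                        f"{chrom}_c{ordinal}",
                        chrom,
                        tuple(g.gene_id for g in chain),
                    )
                )
            else:
                singletons.add(chain[0].gene_id)
    return clusters, singletons
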