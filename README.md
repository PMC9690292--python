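# rgacnv

Copy-number variation (CNV) analysis across resistance gene analogues
(RGAs) in allopolyploid *Brassica napus* (canola, AACC, 2n = 38).

Blackleg (*Leptosphaeria maculans*) resistance in canola is driven largely
by RGAs — NLR, receptor-like kinase (RLK) and receptor-like protein (RLP)
genes — and deletions or duplications of these genes can create or destroy
resistance. `rgacnv` is the post-processing side of a read-depth CNV study
of such genes: starting from CNVnator-style call files for a panel of
cultivars, a gene annotation (GFF3) and per-gene protein-domain profiles,
it produces filtered calls, gene-level CNV events, RGA class assignments,
physical clusters, cross-cultivar summary tables, resistance-locus
breakdowns and a neighbour-joining sample phylogeny.

## What it computes

* **Call filtering.** A call is removed when its e-value ≥ 0.05 *or* its
  fraction of zero-mapping-quality reads q0 ≥ 0.5 (both boundaries
  inclusive), and when it reciprocally overlaps an assembly N-gap by ≥ 50%
  of both call and gap (bedtools `intersect -f 0.50 -r -v` semantics,
  per gap feature).
* **Gene association.** A gene gains a CNV event of type *t* in sample *s*
  when a single filtered call of type *t* covers ≥ 50% of the gene's
  length (`-f 0.50`, no summing across calls).
* **RGA classification.** A decision ladder over domain sets: NB-ARC
  combinations yield NBS/TNL/TN/CNL/CN/NL (or OTHER with extra domains),
  TIR without NB-ARC yields TX, a transmembrane segment plus an LRR or
  LysM ectodomain yields RLK (with kinase) or RLP (without).
* **Physical clustering.** RGAs within ±10 annotated genes of each other
  (rank distance, transitive chaining) form clusters; the rest are
  singletons.
* **Summaries.** Per-cultivar deletion/duplication/"both" counts and
  percentages, the pairwise shared-RGA matrix, the cultivar-sharing
  histogram, per-chromosome and per-A/C-sub-genome distributions and size
  bins.
* **Resistance loci.** Marker-anchored locus regions (explicit coordinates
  or exact primer-pair placement), with per-class candidate and
  CNV-affected RGA counts.
* **Phylogeny.** Pairwise allele-difference distances
  d(i,j) = mean |gᵢ − gⱼ| / 2 over co-observed biallelic sites, followed by
  Saitou–Nei neighbour joining.

Because no sequencing data are distributed with the original study, the
package ships a synthetic-data generator (`rgacnv.simulate`) that emits
every input with planted truth — reference with N-gaps, annotation, domain
tables, per-sample call files with noise engineered to fail each filter,
markers copied from the reference, and genotypes evolved along a known
tree — so the whole pipeline is testable end to end.

## Worked example

```bash
rgacnv simulate --seed 7 --out bundle
rgacnv summarize --calls-dir bundle/calls --gff bundle/genes.gff3 \
    --domains bundle/domains.tsv --gaps bundle/gaps.bed \
    --markers bundle/markers.tsv --reference bundle/reference.fasta \
    --genotypes bundle/genotypes.tsv --out reports
```

prints

```
96 gene events across 46 RGAs; reports in reports
```

and `reports/table1.tsv` begins

```
sample	deletion	deletion_pct	duplication	duplication_pct	total	both	both_pct
Ascona	8	66.67	4	33.33	12	6	50.0
English_Giant	9	75.0	3	25.0	12	8	66.67
```

Each row is one cultivar: the number of filtered CNV calls supporting at
least one RGA event, split into deletions and duplications with their
percentages of the cultivar's total, and the "both" column — events whose
RGA is deleted in some cultivar and duplicated in another. The other
reports hold the shared-RGA matrix (`table2.tsv`), the sharing histogram
(`table3.tsv`), chromosome/sub-genome/size distributions, the per-locus
breakdown (`table4.tsv`) and the NJ tree (`tree.nwk`).

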