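# Methods

## Coordinate conventions

All intervals inside the package are 0-based half-open. GFF3 and
CNVnator coordinates (1-based inclusive) are converted on read; BED gap
tracks pass through. Reported Mbp and kb values are rounded half-up to
2 decimals, matching the convention of printed report tables (Python's
builtin banker's rounding would disagree on exact ties). Sub-genome
labels are derived from chromosome names: an `A` or `C` immediately
followed by a digit, with or without a `chr` prefix, case-insensitively;
anything else (scaffolds, contigs) is excluded from sub-genome tallies.

## Call filtering

The quality filter removes a call when `e_value >= 0.05` **or**
`q0 >= 0.5`. The two criteria are independent unreliability flags — a
weak read-depth signal and repeat-confounded mapping respectively — so
the disjunctive reading is the one that actually reduces false
positives; a conjunctive reading would keep a call with e = 0.9 as long
as its q0 were low. Both boundaries are inclusive. Of CNVnator's four
e-value columns the first (the primary t-test statistic) is thresholded.
A q0 of −1 is CNVnator's "no reads" sentinel; it encodes absence of
evidence rather than mapping ambiguity, so such calls pass the q0
criterion and are flagged in the log instead.

The gap filter reproduces `bedtools intersect -f 0.50 -r -v` against the
N-gap track: a call is removed when some *single* gap feature covers
≥ 50% of the call and the call covers ≥ 50% of that gap. The test is per
feature, never against the union of gaps — two adjacent gaps covering
30% each do not combine to 60%. Gap tracks are merged and sorted on
construction, so overlapping input features behave like bedtools' merged
output.

## Gene association

A gene gains an event of type *t* in sample *s* iff a single filtered
call of that type and sample covers at least half of the gene
(`-f 0.50` applies to each intersect pair, so fragmented sub-threshold
coverage never qualifies; the boundary is inclusive, following the
executable `-f 0.50` over the looser prose "more than 50%").
Duplicate qualifying calls collapse to one event per (gene, sample,
type) with all supporting call ids retained.

Event-level counting in the per-cultivar table follows the same logic:
a filtered call is counted once per sample iff it supports ≥ 1 RGA
event; a call spanning two RGAs still counts once. The per-sample
"both" column counts that sample's counted calls whose supported RGA has
cross-sample status *both* (deleted somewhere, duplicated somewhere).
A gene deleted and duplicated within the same sample also has status
both; the same-sample case is rare and intentionally not distinguished
in the partition.

## RGA classification and clustering

Classification is a pure function of the domain set. With NB-ARC
present: any domain outside {TIR, CC, NB-ARC, LRR} → OTHER; otherwise
TIR beats CC, and the LRR decides TNL/TN vs CNL/CN; LRR alone with
NB-ARC → NL; bare NB-ARC → NBS. TIR without NB-ARC → TX. Without NLR
evidence, a transmembrane segment plus an LRR or LysM ectodomain gives
RLK (kinase present) or RLP (kinase absent). NLR evidence always takes
precedence over the receptor patterns. TX is counted in the NLR family.

Clustering measures distance in gene-rank units over *all* annotated
genes of a chromosome (rank = position in start-coordinate order, ties
broken by end then gene id). RGAs whose consecutive rank differences are
≤ 10 chain transitively; a difference of exactly 10 still chains
("within ±10 genes"). Maximal chains of ≥ 2 members are clusters, named
`<chrom>_c<ordinal>` in coordinate order; chains of one are singletons.
Clusters may mix subclass families — co-membership of a subfamily is an
empirical observation, not a rule.

## Resistance loci

A marker is anchored either by explicit coordinates (which take
precedence) or by exact matching of its primer pair: the forward primer
and the reverse-complemented reverse primer on one chromosome, in
order, within a 10 kb amplicon, in either orientation. Exactly one
compatible placement is required; zero or several placements drop the
marker with a logged reason. Mismatch-tolerant alignment is deliberately
out of scope — synthetic references carry their primers verbatim, and
real-world users are expected to supply coordinates. A locus region is
the union span of its markers (single chromosome enforced). Candidate
RGAs overlap the region by ≥ 1 bp — locus membership, unlike CNV
association, is not a 50% criterion — and candidates with ≥ 1 event are
"affected", tallied by status (del/dup/both) so tallies sum to the
affected count.

## Phylogeny

The genotype distance is the mean allele difference per co-observed site,
|gᵢ − gⱼ|/2 averaged over sites where neither call is missing: bounded
in [0, 1], robust to missing data, and proportional to path length under
the simulation's substitution process. A pair with no co-observed site is
an error naming the pair. Neighbour joining is the standard Saitou–Nei
agglomeration: join the pair minimising
Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), branch lengths by the split
formula, matrix reduction d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties in Q
are broken by the smallest index pair; negative branch-length estimates
are clamped to zero with the pre-clamp value logged. The tree is left
unrooted — the final join is kept as a root trifurcation — and
serialised as newick through Bio.Phylo. For n = 2 the single edge is
emitted as two half-length child branches, preserving the leaf-to-leaf
path length.

## Synthetic data

The generator emulates the study design at desk scale with one seed
driving every draw (identical seeds give byte-identical bundles):

* **Genome.** 10 A + 9 C chromosomes. Gene lengths ~ U(1, 5) kb with
  intergenic spacing ~ U(0.5, 5) kb, giving ~Mbp-scale chromosomes that
  are auto-sized unless `chrom_len` is fixed (over-full packing is an
  error). N-gaps (0.2–1.5 kb) are placed in intergenic space at 20 per
  Mbp — a rate chosen so each desk-scale chromosome carries a couple of
  gaps for the gap filter to act on.
* **Genes.** 500 genes, 10% RGAs. The RGA fraction is deliberately below
  a naive scale-down of the real annotation: under a ±10-gene window,
  RGA densities much above ~10% would chain nearly all RGAs into
  per-chromosome mega-clusters and erase the cluster/singleton
  structure the analysis is about. Groups are planted directly as truth:
  ~40% singleton draws, clustered members 1–3 ranks apart, successive
  groups separated by more than the window. Class labels realise the
  configured mix exactly (largest-remainder apportionment) with RLK
  dominant, and each label's domain set is the minimal architecture the
  classifier maps back to that label; non-RGA genes draw decoy profiles
  (bare kinase, bare TM, bare LRR, unknown, empty).
* **Calls.** Planted events (12 per sample by default, deletion
  probability 0.62 echoing the genome-wide deletion excess) produce one
  call covering the stated fraction of the gene from its start, with
  passing statistics (e ~ U(1e-12, 1e-3), q0 ~ U(0, 0.3)). Noise calls
  fail the quality filter by construction — e ∈ {0.05, 0.5} or
  q0 ∈ {0.5, 0.9}, exercising both inclusive boundaries — and
  gap-artifact calls coincide exactly with a planted gap so the
  reciprocal filter removes them. Planted calls never leave their gene,
  so they cannot create unplanned associations.
* **Markers.** Loci are anchored on an RGA and span a few genes.
  Even-numbered loci carry two primer-pair markers whose 20-mers are
  copied from the reference (uniqueness verified genome-wide, windows
  shifted off N-runs); odd-numbered loci use explicit coordinates,
  exercising the precedence path.
* **Genotypes.** Evolved along a fixed 8-cultivar tree (or a random one
  for other sample counts): each branch of length *b* toggles
  Poisson(b·n_sites) uniformly chosen sites between homozygous states 0
  and 2; 1% of calls are masked as missing; monomorphic sites are
  dropped before writing. Back-mutation is possible but negligible at
  the default branch lengths.

What the generator does **not** model: read-level noise (calls are
either cleanly planted or cleanly failing), linkage disequilibrium,
heterozygous genotype calls, transposon-driven call artefacts, and
fractional gene coverage by real breakpoints. Passing the planted-truth
suites therefore demonstrates that the post-processing logic is correct,
not that upstream CNV calling on real reads would be.

## Problem sizes and numerical choices

The shipped test and acceptance workloads use the default bundle
(8 samples, 500 genes, ~190 calls), 100–1,000-case random fixtures for
the brute-force oracles, and 100 seeded replicates at 5,000 sites for NJ
topology recovery — sizes chosen so the full suite completes in a few
seconds while leaving each property statistically meaningful.
Floating-point comparisons in reports go through the half-up rounding
helper; everything else is exact integer arithmetic. Distance matrices
are validated (symmetry, zero diagonal, non-negativity) before NJ runs.

## Known limitations

* Primer placement is exact-match only; no mismatch or indel tolerance.
* GFF3 handling is gene-feature-only by design (no mRNA/CDS hierarchy).
* The per-sample "both" column definition is one of several defensible
  readings of a cross-tabulated report; the chosen reading ties it to
  the gene-level status partition.
* NJ is O(n³) with a dense matrix — fine for cultivar panels, not for
  thousands of samples.
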