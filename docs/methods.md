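# Methods

`repskim` reimplements, at desk scale, the analysis chain used to survey a
plant repeatome from genome-skimming data: similarity-graph clustering of
low-coverage paired-end reads, repeat quantification against genome size,
tandem/5S rDNA cluster-graph typing, a per-read sequence-diversification
statistic (Hs/Ho), and a repeat-based phylogenomic consensus network.
Because the original skim reads of such surveys are rarely deposited, the
package carries a first-class synthetic-data generator that plants exact
ground truth, so every stage is testable end to end without downloads.

## Read simulation

A *monoploid blueprint* is a random background sequence plus repeat
families.  Dispersed families (LTR retrotransposon and DNA-transposon
lineages) place `copies_per_monoploid` mutated copies of a family
consensus at random background positions; tandem families (satellites)
and each 5S ribotype form one head-to-tail array.  Every copy receives
independent per-base substitutions at the family's `divergence` (0–0.25);
5S units are a conserved gene (default 120 bp) plus one intergenic spacer
(IGS) per ribotype.  A holoploid genome is the concatenation of `nx`
monoploid complements, so allo- and autopolyploids are built by passing
divergent or duplicated blueprints.  Skimming draws
`floor(coverage × G / (2 × read_length))` uniform fragments (default
2×101 bp reads, inserts uniform on 123–329 bp), reverse-complements the
second mate and applies substitution errors (default 0.5%); indels, PCR
duplicates, GC bias and quality-score structure are deliberately not
modelled.  All randomness flows from one integer seed through a
splittable generator; identical specs give byte-identical FASTA/FASTQ.

Planted truth records every interval, so the generator can report exact
genomic proportions and per-read majority provenance.  Two deliberate
idealizations keep the recovery experiments interpretable:

* **Insertion-site spacing.** Blueprints accept a `site_spacing` (0 by
  default, i.e. fully uniform placement).  The bundled experiments use
  300 bp: without it, chains of physically overlapping reads across
  nearly adjacent insertions of *different* families fuse their clusters
  at ≥0.4× coverage, which confounds per-family scoring.  Real genomes do
  nest repeats; this is a controlled-conditions choice, not a claim about
  biology.
* **Evenly interspersed between-sample divergence** (Hs/Ho experiment
  only, below).

## Similarity graph and clustering

Two reads are joined when some ungapped overlap alignment (either
orientation) reaches ≥55 bp with ≥90% identity computed over the overlap
— the standard contract for graph-based repeat clustering of skim reads.
Candidate pairs are seeded by shared 13-mers (both strands, canonical
form) and every candidate is verified exactly at its k-mer-implied
offset, so reported hits never violate the contract; a quadratic
all-offset scan (`brute_force_hits`) acts as the independent oracle and
agrees exactly with the seeded finder on error-free data (and on 200-read
simulated fixtures in the tests).  The overlap model is ungapped because
the thresholds are stated as identity-over-overlap; this also keeps the
oracle exact.

Clusters are connected components, ranked by size (ties broken toward the
smallest member id), with singletons reported as unclustered and a
cluster-size cut of 0.01% of the analysed reads (held with ≥ at the
boundary).  Optional modularity-based community refinement (Louvain) is
available but off by default.  For large datasets (the 59,400-read
quantification benchmark) the pipeline uses `cluster_streaming`: it walks
the shared-k-mer buckets, orders members along the implied alignment
axis, and union-finds through exact verification of consecutive
(maximum-overlap) and farthest-admissible (minimum-overlap) neighbours
instead of materializing the full edge list.  Each merge still satisfies
the 90%/55 contract; in the deep-coverage regime of repeat clusters the
resulting partition matches the full construction (tested), at a fraction
of the memory.

An organelle pre-filter mirrors k-mer read screening: a pair is dropped
when either mate shares ≥2 24-mers (either strand) with the organelle
reference.

## Quantification

Cluster annotation is a per-read k-mer plurality vote (k = 13, both
strands) against a user-supplied labelled repeat library; a cluster takes
the winning lineage when the vote fraction reaches `min_vote` (0.5),
otherwise it is Unclassified.  Genome proportion of a lineage in a sample
is that sample's reads in clusters of the lineage divided by its analysed
reads; absolute amounts multiply by the monoploid genome in Mbp.

Genome-size arithmetic: 1Cx = 2C/nx rounded half-up to 3 decimals
(tetraploids carry four monoploid complements per unreplicated somatic
nucleus; the source survey uses "holoploid" for the 2C figure and the
package follows that usage); pg→Mbp uses 978 Mbp/pg with flooring at each
step, and monoploid Mbp = floor(holoploid Mbp / nx).  These conventions
reproduce the published worked values (3690/922 and 551/275 Mbp, and the
6.7-/3.3-fold ranges) exactly.  One row of the bundled 44-accession
sample table (the *B. hybridum* accession) prints 1Cx = 2C/2 instead of
2C/nx and therefore fails its own table's rule; the package recomputes
honestly and flags the row rather than patching it.

## Tandem and 5S graph typing

The connected-component index C of a cluster is the fraction of its reads
in the largest component of its subgraph — near 1 for intact tandem
clusters.  Monomer consensus reconstruction sweeps k ∈ {11,15,19,23,27}:
for each k the directed k-mer frequency graph (reads plus their reverse
complements) is walked greedily from the heaviest k-mer along heaviest
successors (frequency ≥2) until a k-mer on the path repeats (cycle) or
the walk dies (non-tandem flag).  The k-mer coverage score is the
frequency mass of the cycle's k-mers (each canonical k-mer counted once,
both orientations) over all k-mer mass; the k maximizing coverage wins,
and the consensus is one linear monomer of the cycle.  The denominator
includes all k-mers, noise included (the alternative — thresholding the
denominator — is not recoverable from published tables and would only
raise the score).  Greedy cycle extraction stands in for full
path-optimization consensus machinery, which is out of scope; the k-sweep
mimics its model selection.

5S typing formalizes loop counting: reads matching the conserved gene
exemplar (≥80% identity over ≥40 bp, both strands) form the junction and
are set aside; the remaining IGS reads are re-clustered under the
standard 90%/55 contract, and sub-clusters holding ≥5% of the cluster
count as loops; graph type = clamp(loop count, 1, 3).  The 40 bp gene
threshold is deliberately below the 55 bp edge threshold, so any read
able to bridge two ribotypes through shared gene sequence has already
been removed, and singleton chimeras cannot create spurious loops.
Recovery is 1/2/3 loops for 1/2/3 planted ribotypes in ≥18/20 seeded runs
per count (tested at 20/20).

## Hs/Ho diversification landscape

For each read of an annotated cluster, Hs counts its edges to same-sample
reads and Ho its edges to other samples; Ho is normalized by
(n_same − 1)/n_other analysed-read totals so unequal coverage cancels,
and reads with Hs = 0 or Ho = 0 are excluded but reported (private
families surface as exclusions, not as infinite ratios).  Histograms of
log10(Hs/Ho) use fixed 0.1-wide bins on [−3, 3] (outliers clipped into
the edge bins so counts always sum to the records).

The benchmark plants one family with a shared consensus (mode expected at
0) and one whose consensus differs by 8% between the two samples.  The
8% of fixed differences are placed *evenly interspersed* along the
monomer: with random placement, 10–15% of alignment windows happen to
fall under the 10% mismatch ceiling, and those locally conserved windows
blur the cross-sample edge deficit the statistic is supposed to detect
(measured during design; the mode then wanders below 0.5 in about half
of the seeds).  Even spacing realizes the intended condition — uniformly
diverged sequence — and the diverged mode sits stably near +1.8.
Within-sample copy heterogeneity (3%) keeps same-sample pairs well under
the ceiling.

## Repeat-based phylogenetics

For each cluster, observed edge counts between sample pairs are divided
by their expectation under uniform random edge placement given per-sample
node counts: expected(s,t) = E·n_s·n_t/P off-diagonal and
E·C(n_s,2)/P on it, with P the number of unordered node pairs (the
"observed/expected" similarity measure named, but not formalized, in the
tradition this follows).  Clusters missing a sample or with a zero
off-diagonal entry are excluded, never imputed; distance = 1/(obs/exp)
using off-diagonal entries only.  Neighbor joining is the classical
Q-criterion algorithm with deterministic tie-breaking (lexicographically
smallest label pair) and negative branch lengths clamped to zero with the
deficit shifted to the sister branch; on additive matrices it reproduces
the input metric to 1e−9 (tested on 100 random 8-leaf trees, and
cross-checked against an independent NJ implementation).  Per-cluster
trees are condensed into a consensus split network: splits with support
≥`min_support` (default 0.1, standing in for stock consensus-network
defaults) are retained with mean branch length as weight, trivial splits
always included, and written as a SplitsTree-consumable nexus splits
block.

The recovery benchmark evolves 10 repeat families along a six-taxon
three-cherry species tree (cherry branches 0.01, central branches 0.03
substitutions/site, within-species copy divergence 0.005) over 600-kb
diploid genomes at 0.15×; all three cherry splits reach support ≥0.5 in
≥8/10 seeded runs (observed 10/10).

## Statistics

Pearson correlations of per-lineage Mbp amounts with 1Cx use the exact
t-transform p (n−2 df).  The contribution of a repeat to pairwise
genome-size differences is (A_i − A_j)/(GS_i − GS_j)×100 over all pairs
oriented so the size difference is positive, per-pair negatives floored
at zero by default (a signed variant is available): flooring is the only
reading consistent with published tables that report 0% contributions
for lineages with positive size correlations.  Kruskal–Wallis tests are
tie-corrected H with the chi-square approximation (via scipy); the null
rejection rate at α = 0.05 is calibrated within 3 binomial SD over 1,000
replicates, and the chi-square p agrees in ordering with the exact
permutation p at small n (tested).

## Problem sizes and error bands

The experiments are sized to keep the whole suite within minutes on one
CPU while leaving the statistical bands meaningful: the quantification
benchmark uses three diploid samples of 10-Mbp monoploids at 0.1×
coverage (59,400 reads, 9,900 pairs/sample), scored in binomial standard
deviations with read *pairs* as the sampling unit — mates of one pair
fall in or out of a (≫ insert-length) family together, so the pair is
the independent draw.  The 5S, Hs/Ho and network benchmarks use 40–600 kb
genomes at 0.15–0.5×, where repeat-cluster read depth (20–60× per
monomer), not genome size, is what the methods are sensitive to.  Passing
these tests shows the machinery is correct and calibrated under the
stated conditions; it does not certify behaviour on real skim data with
quality artifacts, indels, organelle load or nested repeat structure.

## Known limitations

Ungapped overlaps only (no indel tolerance); annotation is k-mer voting
against a user library, not protein-domain classification; the streaming
clustering guarantees each merge's contract but not edge-list
completeness (it is used only where components, not edges, are needed);
5S typing reports at most 3 loops; no graphical layout of cluster graphs
is produced.
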