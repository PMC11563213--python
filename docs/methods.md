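# Methods

This note documents the models, statistics and design choices behind the
pipeline, in enough detail to judge what a result does and does not mean.

## Problem setting

Genome-wide association in a very small cohort (the motivating design is
11 cases vs 60 controls) is underpowered at the single-SNP level: true
signals hide among false positives at any usable threshold. The pipeline
deliberately keeps a permissive SNP threshold (p < 0.05), then demands
*network coherence* — selected genes must form connected, collectively
extreme modules of a protein–protein interaction (PPI) network — and
*pathway convergence* — modules must over-represent annotated pathways —
before a signal is reported. A second omics layer (proteomic
differential-expression p-values from the same individuals) runs through
the identical network/enrichment machinery, and pathways found by both
layers are promoted by Fisher's combined probability test.

## Quality control and association

* Sample filter: call rate strictly greater than 0.98 (the boundary value
  0.98 itself is removed — the contract is "more than").
* SNP filters, applied in a fixed order with the first reason recorded:
  Y chromosome (labels `Y`, `chrY`, `24`, case-insensitive), call
  rate < 0.95, minor allele frequency < 0.01 computed on non-missing
  alleles after sample filtering.
* LD pruning: per chromosome, a sliding window of 50 SNPs advancing by 5;
  within a window, any pair with squared Pearson correlation of genotype
  codes (pairwise-complete) above 0.5 loses one member — the lower call
  rate, ties broken by removing the larger position — repeated until the
  window is stable. Window/step are PLINK-conventional defaults; the keep
  rule is a deterministic choice made here.
* Association: Pearson chi-square on the 2×3 case/control × genotype
  table. Genotype columns with zero total are dropped and df reduced to
  (columns − 1); a fully missing SNP reports p = 1 with a flag; expected
  counts below 5 set a `low_expected` flag (no continuity correction).
  The chi-square approximation is visibly discrete below roughly 100
  samples per group; null p-values are uniform to a KS test at 250+250.

## Gene-level scores

Each selected SNP maps to the highest-priority candidate gene in the
user-supplied SNP→gene table (priority ties go to the lexicographically
smallest gene id; unmapped SNPs are dropped and counted). Gene p = minimum
over assigned SNP p-values; a Fisher-within-gene alternative exists behind
`strategy="fisher"`. Min-p is deliberately anti-conservative at the gene
level — the network and enrichment stages, not the gene score, carry the
error control. The proteomic table is thresholded at p < 0.05 on input,
duplicates collapse by minimum, and all p-values are floored at 1e-300.

## Active-subnetwork search

Scores enter as z = Φ⁻¹(1 − p) (p clamped to [1e-300, 1 − 1e-16]); only
genes present in the PPI network participate. A connected set A of size k
has raw score z_A = Σᵢ zᵢ/√k and calibrated score
s_A = (z_A − μ_k)/σ_k, with (μ_k, σ_k) estimated from 1000 Monte-Carlo
random k-subsets of the scored genes (one permutation per sample, prefix
sums give every k at once; k beyond the table is linearly extrapolated).

Search is greedy: from each seed, repeatedly add the neighbouring scored
gene that maximises s_A while s_A strictly improves, up to `max_depth`
additions (default 2·⌈√n⌉). Seeds are the top `n_seeds` genes by z, or —
when an rng is supplied, as the iterated pipeline does — a random draw of
`n_seeds` from the top 5·`n_seeds`, so repeated runs explore different
starting points. Modules are extracted successively: the best module is
recorded, its genes removed from the scored set, and the search repeated
(calibration stays fixed on the full set) until the best remaining module
is background-level or a round limit is reached. Successive extraction is
what yields several distinct modules when one dominant region would
otherwise absorb every seed. Finally, modules are filtered to pairwise
overlap ≤ 50%, overlap measured as |A∩B|/min(|A|,|B|), boundary inclusive.

Two properties of this statistic are worth knowing. First, on a score
table where *every* gene is significant (as after a p < 0.05 input
filter), the calibration mean grows as μ_k = z̄√k, so a sufficiently
extreme singleton can be unbeatable — randomised seeds plus iteration
minima are the mitigation, not a fix. Second, the optimal module under
Σz/√k provably excludes members whose z falls below roughly half the
module mean; recovered modules are therefore the *strong core* of a
planted module, not its full membership. With signal p ~ Beta(0.05, 1) on
a 20-gene module, about three genes sit below that bar in a typical draw,
which caps the top module's Jaccard with the full planted set near
0.55–0.8; across seeded replicates roughly three-quarters of runs reach
Jaccard 0.6. Greedy growth itself attains ≥ 90% of the exhaustive optimum
over connected subsets on small graphs when every node may seed (verified
by enumeration in the test suite).

## Enrichment and iteration

The background universe N is the set of genes present in both the PPI
network and the layer's score table: the hypergeometric draw models
subnetwork membership, which is only possible for scored network genes.
For each module and each pathway with at least one overlapping gene, the
exact two-sided hypergeometric p is min(1, 2·min(P[X ≥ x], P[X ≤ x]))
(minimal-tail doubling; a one-sided over-representation switch exists),
Bonferroni-multiplied by the number of pathways tested for that module.
Per pathway the smallest corrected p across modules is kept, filtered at
p < 0.05; gene lists union on exact ties. The full search+enrichment
stage runs `n_iter = 10` times with child seeds of one seed sequence, and
per-pathway minima over iterations are reported — the aggregation is
monotone: more iterations can only lower a pathway's p. Iterating minima
over randomised searches is a sensitivity device, not an error-controlled
procedure; reported p-values are comparable within a run, not calibrated
tail probabilities.

## Merging and clustering

Shared pathways combine as X² = −2(ln p_g + ln p_p) against chi-square
with df = 4, evaluated in log space (inputs to 1e-300 are safe; results
floor at 1e-300). The combination amplifies two comparable small
p-values — for p_g = p_p = t the merged p is below t exactly when
t(1 − 2 ln t) < 1, i.e. t < 0.0916 — but a severely asymmetric pair can
merge *above* its smaller member (the weaker layer dilutes). Single-layer
pathways pass through unchanged, so the merged ranking mixes two- and
one-layer evidence by design.

Clustering uses exact set arithmetic for the overlap-index matrix,
Pearson correlation of full OI rows (self-entry included; a switch
excludes it) for distances PD = 1 − R, with the convention R = 1 for two
identical zero-variance profiles and R = 0 otherwise. PD may exceed 1;
average linkage accepts that. The agglomeration is implemented directly
(≈40 lines) because the contract fixes a deterministic smallest-index
tie-break between equidistant pairs, which library linkage routines do
not guarantee; it matches scipy's average linkage exactly on tie-free
inputs. The dendrogram is cut at PD = 0.55 and each cluster's minimum-p
pathway (ties to the smallest id) becomes its representative.

## Synthetic data

The generator emulates the study design rather than any specific dataset:

* Cohort: 11 cases / 60 controls by default (power at that size is
  intentionally poor — that is the design's premise); recovery tests use
  250/250, chosen as the smallest round size at which the chi-square
  null is clean and planted effects of δ = 0.25 are reliably detectable.
* PPI: Barabási–Albert preferential attachment at mean degree 4, node ids
  `G000001`…; connected by construction.
* Pathways: uniform random gene sets, except *planted* pathways, which
  draw 85% of their genes from one connected frontier-grown neighbourhood
  (the rest uniform). Planted neighbourhoods are pairwise disjoint, avoid
  the top-decile-degree hubs, and are densified to mean internal degree 4.
  All three choices are what make planted modules behave like disease
  modules: dense enough to stay connected when a quarter of their genes
  fall below the input p-filter, and separated enough that distinct
  modules do not chain into one through shared hubs.
* Genotypes: null SNPs Binomial(2, f), f ~ Uniform(0.05, 0.5), identical
  between groups; SNPs whose top-priority gene lies in a planted genomic
  pathway shift the case allele frequency by `effect_delta` (additive
  shift, clamped to [0.01, 0.99]; chosen over an odds-ratio
  parameterisation for transparency). Fractions of SNPs are labelled
  chromosome Y, degraded below 95% call rate, or duplicated in place
  (r² = 1 with their neighbour) to exercise each QC filter; LD beyond
  duplicated columns is not modelled.
* Proteomics: genes of planted proteomic pathways draw p ~ Beta(a, 1)
  (default a = 0.1, mean a/(a+1) ≈ 0.09); all others Uniform(0, 1).
* Every artefact is a deterministic function of one seed.

What passing recovery tests show: the pipeline finds dense, separated,
strongly scored planted modules and ranks their pathways correctly. What
they do not show: behaviour under linkage disequilibrium structure,
population stratification, correlated protein measurements, annotation
bias, or modules that overlap each other — none of which the generator
emulates.

## Scale of the shipped experiments

The end-to-end recovery experiment runs at 500 genes, 5000 SNPs, 250
cases/controls, 30 pathways (7 planted), 10 iterations — about 80 s on
one core; module-recovery replicates (50 seeded runs at 500 genes) take
about 10 s. These sizes were chosen so the full suite exercises every
stage at meaningful power while remaining routine to run.

## Known limitations

* Greedy growth with strict improvement finds strong cores, not full
  modules (see above); simulated annealing, the classical alternative, is
  out of scope.
* Bonferroni is per-module ("pathways tested for this subnetwork"), the
  narrow reading; a collection-wide switch exists.
* Min-over-iterations aggregation and min-p gene collapse are both
  anti-conservative by construction; final p-values order pathways but
  should not be read as calibrated significance levels.
* Identifier namespaces are opaque strings; the mapping files must supply
  a consistent namespace across score tables, network and pathways.
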