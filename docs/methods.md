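# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `g2e`, and what the synthetic benchmarks do and do
not establish about real data.

## Reference network and gene sets

Links between gene families carry integer evidence scores in
[0, 1000]. The network retains links with score **strictly** above
the critical value 275. Strictness matters because clustering weights
are unit-based normalized, w = (s − 275)/(1000 − 275): a score of
exactly 275 would map to weight 0, an edge invisible to the
clustering, so including it would only blur the network contract.
Families with no retained link are excluded from the node set; they
can never join a multi-family gene set, but they remain visible to
the similarity index through the genome content table.

Gene sets come from Markov clustering (MCL) of the weighted network.
MCL alternates expansion (matrix squaring) with inflation (entrywise
power, then column renormalization) on the column-stochastic
transition matrix until the largest entrywise change falls below
1e-6 (at most 100 iterations; non-convergence warns and interprets
the current matrix). Implementation choices, each made for
determinism or numerical robustness:

* a self-loop on every node with weight equal to its maximum incident
  edge weight, added before normalization — damps odd/even flow
  oscillation on bipartite-ish structures;
* entries below 1e-5 are pruned after each inflation and columns are
  renormalized, keeping the matrix sparse without visibly changing
  converged attractors (the same 1e-5 is used when reading attractor
  structure, so near-converged residual flow cannot spuriously merge
  attractor systems);
* clusters are the connected attractor systems of the converged
  matrix; a non-attractor node joins the system receiving the most of
  its flow, ties broken toward the system containing the
  lexicographically smallest node id; node order is sorted ids. The
  result is a deterministic, true partition, which the averaging in
  the similarity index assumes.

The default inflation of 4 produces fine-grained clusters; the
catalog is filtered to sets of ≥ 4 families before use by the
similarity index.

## The pairwise indices

Genome content similarity averages, over qualifying gene sets, the
fraction of set families with identical presence/absence state in the
two genomes. Three conventions are worth stating explicitly:

* **Joint absence counts as a match.** The per-set score measures
  agreement of phyletic pattern, not shared possession; the worked
  example in the package (four matching of eight families → 0.5)
  counts one jointly absent family among the matches.
* **A set qualifies if present in at least one genome**, presence
  meaning ≥ 5% of its families (inclusive boundary). This excludes
  sets absent from both genomes, which would otherwise contribute
  perfect agreement and inflate the index for small genomes.
* **Averaging is unweighted** across sets, so large sets cannot drive
  the genome-wide score.

The functional association index uses the two-genome induced network
with edges unweighted. Its denominator is the edge count among
*exclusive* families only (A–A + A–B + B–B). The three classes
touching "both"-labeled nodes are excluded: links realizable inside a
single genome say nothing about cross-boundary interaction potential,
and including them would make the index decay trivially with genome
overlap. Undefined values (no qualifying set; no exclusive-exclusive
edge) propagate as NaN, never 0 — 0 is a meaningful value for both
indices. The self-pair of the association index is undefined by
construction and recorded as missing.

## Ecological matrices

OTU tables are binary. Filtering (OTUs in < 3 samples, samples with
< 3 OTUs) iterates to a fixed point: removing an OTU can push a
sample below threshold and vice versa, and the fixed point is the
only state satisfying both rules simultaneously; a single pass is
order-dependent. Filtering is therefore idempotent. Jaccard
co-occurrence is intersection over union of sample profiles; an empty
union is undefined (NaN). Cophenetic distances are path sums of
branch lengths between leaves; trees may be unrooted since root
placement does not change path sums.

## Permutation statistics

All matrix tests unfold aligned lower triangles into vectors. Pairs
missing in any matrix of a joint analysis are masked out of all
vectors; the mask is fixed by the observed matrices. More than 50%
missing entries is treated as an error rather than an analysis.

The Mantel statistic is the Pearson correlation of unfolded vectors;
the null distribution comes from simultaneously permuting rows and
columns of the first matrix, which preserves the dependence structure
within each matrix while breaking the association between them
(objects, not pairs, are exchangeable). The partial statistic is the
first-order partial correlation r_AB·C, recomputed per permutation of
A with r_BC held fixed. Conditioning on a matrix identical to B
returns 0 (the algebraic limit of 0/0); conditioning on a matrix
perfectly correlated with A or B otherwise raises an error.

Matrix regression (MRM) fits OLS of the unfolded response on unfolded
predictors with intercept. Coefficients, t statistics, R² and F are
classical; p-values come from permuting the response matrix and
recomputing the statistics — two-sided on |t| for coefficients
(negative slopes are meaningful), one-sided for F. Collinear designs
(condition number > 1e10) are rejected. Nested-model R² differences
("variance explained by the genomic index beyond phylogeny") are
computed from two separate fits.

Conventions: one-sided (greater) Mantel tests; +1 smoothing, so the
smallest attainable p is 1/(n_perm + 1) — 0.0001 at the default
9999 permutations, which is why that default was chosen. Similarity
matrices enter as similarities; the sign of r is interpreted
directly. With a fixed seed every result is bit-reproducible; the
permutation engine is vectorized in chunks of 500 permutations.

These statistics are also available from R (vegan, phytools); the
test suite pins this implementation to values computed with those
packages on a frozen fixture, to twelve decimals.

## Gene-set screen

The screen asks which individual gene sets distinguish a co-occurring
focal genome pair from a non-co-occurring contrast pair: sets of
≥ 8 families with per-set similarity ≥ 0.6 and *representation*
≥ 0.6 for the focal pair, minus sets passing the same criteria for
the contrast pair. Representation is defined here as the fraction of
the set's families present in the union of the two genomes: it
separates "the pathway is substantially there" from "the two genomes
agree about it" (which similarity already measures), and avoids
duplicating the 5% presence rule. Output order is deterministic
(sorted set ids). Raising any threshold can only shrink the focal
pass-set; the final list is a set difference, so monotonicity holds
per pair, not for the difference.

## Synthetic data generator

The generator produces coupled datasets exhibiting the structure the
indices exploit; it is a model of that structure, not of any real
community.

* **Tree**: pure-birth (Yule) with `n_genomes` leaves, branch lengths
  scaled so the deepest root-to-tip path is `tree_depth` (default 1;
  0 keeps raw birth-process lengths).
* **Gene content**: each of `n_families` (400) families evolves along
  the tree as a two-state chain with gain and loss rates of 1 per
  unit branch (stationary presence 0.5). Thirty planted sets of 6–14
  families act as functional modules: every member family shares the
  per-set driver chain's gain/loss events (`set_correlation` = 1), so
  modules turn over as units. On top of this, each leaf's family
  calls are flipped independently with probability `content_noise`
  (0.1), emulating strain-level gene content scatter and annotation
  error. The interplay of these two terms reproduces the empirical
  behaviour of the indices: at short phylogenetic distances genomes
  differ by scattered families *inside* shared modules (cross-genome
  functional links among exclusive families are common), while at
  long distances whole-module differences dominate (within-genome
  links among exclusive families swamp the cross links). Both indices
  therefore decay with cophenetic distance, as they should. An
  event-sharing model without the distance-independent noise floor
  produces the opposite (rising) trend for the association index,
  because single module-turnover events contribute within-genome
  edges at rate O(d) while split-module cross edges require two
  events, O(d²).
* **Link table**: within-set pairs are linked with probability 0.9,
  scores uniform on {600..1000}; all other pairs with probability
  0.001, scores uniform on {276..450}. Background scores sit just
  above the retention threshold, so background edges enter the
  network with near-zero weight while planted edges are heavy; the
  planted partition is recoverable by MCL at inflation 4.
* **Ecology**: each sample draws a latent habitat vector
  h ~ N(0, I₅); genome traits are standardized random projections of
  the gene-content matrix onto 5 fixed directions; occupancy is
  Bernoulli with probability sigmoid(logit(0.3) +
  habitat_effect·⟨t, h⟩/√5), then flipped with probability 0.02.
  `habitat_effect` = 0 gives i.i.d. occupancy independent of content
  (the calibration null); the default 5 produces strong habitat
  filtering, under which the partial Mantel test (similarity vs
  co-occurrence given phylogeny) is reliably significant at n = 40
  genomes and 200 samples.

What passing the synthetic benchmarks does **not** show: robustness
to abundance (non-binary) data, horizontal transfer that decouples
gene content from the species tree, unequal genome sizes, biased
taxon sampling, or network scores whose errors correlate with
phylogeny. All of those are properties of real inputs that this
generator deliberately omits.

## Problem sizes and tolerances in the test suite

Oracle-equivalence checks run 100 random small instances per
operation at 1e-12. Permutation calibration uses n = 30 objects, 999
permutations and 200 replicates per test statistic; the habitat
recovery experiments use 100 replicates per arm at 499 permutations
(the p ≤ 0.05 decision needs a resolution of 1/500, and the floor
p = 0.002 leaves margin); distance-decay uses one 60-genome
pangenome. These sizes give stable verdicts for the stochastic
criteria while keeping the default suite quick on a single CPU.
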