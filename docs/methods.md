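# Methods

This note documents the models, algorithmic conventions and design choices
behind `synteny_decay`, and what the simulation-based tests do and do not
establish about real data.

## Gene Order Conservation (GOC)

For two genomes A and B with single-copy BUSCO loci restricted to
chromosomes, let S be the set of gene ids located in both. Within each
genome, genes are ordered per chromosome by (start, end, gene id) — the
gene-id tie-break is arbitrary but deterministic — and genes outside S are
removed *before* windows are formed, so a gene's neighborhood is its two
nearest *shared* genes on each flank. Windows never cross chromosome
boundaries.

A gene g scores |W_A(g) ∩ W_B(g)| / 4 ∈ {0, 0.25, 0.5, 0.75, 1}: a window
gene counts as conserved if it lies anywhere in g's window in the other
genome. This set-intersection rule is symmetric in (A, B) by construction
and treats a locally inverted neighborhood as conserved, which is the
intended behaviour of a gene-order (not gene-orientation) statistic; strand
is ignored throughout. A stricter `same_side` rule (upstream genes must
remain upstream) is available for sensitivity analysis.

Two completeness conventions:

* **strict** (default): only genes with two shared neighbors per flank in
  *both* genomes are scored. All scores are exact quarters, the five score
  categories are well defined, and a genome against itself normalizes to
  exactly 1. Genes near chromosome ends are simply not scored.
* **relaxed**: truncated windows are scored with denominator
  max(|W_A|, |W_B|); useful when many small chromosomes would otherwise
  discard a large fraction of genes.

The pairwise statistic is reported on two scales: `total` (the sum of
per-gene scores, which grows with the number of shared genes) and
`normalized` (mean per-gene score in [0, 1]). Regression defaults to the
normalized scale because it is comparable across pairs with different
shared-gene counts; the total scale is retained for compatibility with
published pairwise GOC matrices. If no gene can be scored the normalized
value is undefined and flagged (`None`), not an exception, so an all-pairs
matrix computation survives degenerate pairs.

Duplicated and Fragmented loci are excluded from GOC (single-copy preset).
For the chromosome-level summaries below, Fragmented loci with coordinates
are included by preset, since chromosome membership does not require a
complete gene model. Fragmented rows lacking coordinates (emitted by some
BUSCO versions) are demoted to Missing at parse time.

## Chromosome assignment and intactness

For a reference genome R and target T, each reference chromosome's shared
genes are tallied by the target chromosome they occupy. Intactness is the
majority fraction — the share of the reference chromosome's genes on its
single best-matching target chromosome. It is invariant to any amount of
within-chromosome reshuffling, which is exactly what makes it complementary
to GOC. Reference chromosomes with fewer than `min_genes` (default 5)
shared genes are excluded: a percentage over a couple of genes is noise.
Ties for the majority target are broken toward the lexicographically
smallest target name and flagged.

## Phylogenetic distance

The predictor is patristic distance on the input tree rescaled to unit
height, where height is the *maximum* root-to-tip path length (input trees
are typically ML trees and not ultrametric, so root-to-tip paths differ;
the maximum is used because "tree height" then has a sharp meaning and the
rescaled tree has height exactly 1). Rescaling divides every branch by one
constant, so all pairwise distances scale together and the correlation
structure of the predictor is untouched. Taxon labels are normalized by
collapsing whitespace to underscores before matching GOC and distance
matrices; mismatched taxon sets are an error, not a silent intersection.

## Decay regression

Observations are unordered within-order taxon pairs (d, y). Cross-order
pairs are excluded by design: they would be dominated by saturation and
would swamp the order-specific signal. Orders with fewer than
`min_taxa_per_order` (default 4) taxa are dropped with a warning — below
that, a per-order slope and intercept rest on fewer than 6 pairs.

Three forms are fitted by OLS on the transformed response (y for linear,
log y for exponential, log y on log d for power). Grouping `by_order` uses
cell-means coding: one intercept and one slope per order, fitted in closed
form per order (the design is block-diagonal). The model F compares the
fit to the intercept-only model **on the same response scale**:
F = (ESS/(2m−1)) / (RSS/(n−2m)). Ranking the three forms by F therefore
compares statistics computed on different response scales (raw vs log);
this is inherent to the "highest F wins" criterion and is flagged in the
report output. Information criteria are deliberately not used — they are
unreliable in distance-matrix regression settings. Observations with y ≤ 0
cannot enter a log model and are dropped with a count; if more than 1% of
pairs would be dropped the fit raises unless explicitly forced, since that
signals a scale problem rather than a few degenerate pairs.

### Permutational inference

Pairwise observations built from matrices are not independent, so F is
referred to a permutation null rather than an F distribution. One
permutation draws a uniform random permutation π of all taxa and reindexes
the GOC matrix as G[π(i), π(j)] — the tree, the distances and the order
classification stay fixed — then rebuilds the within-order pair set and
recomputes the statistic. This is a global (across-order) relabeling;
branch lengths are intentionally not constrained, because distance is the
explanatory variable under test. The p-value is the add-one estimator
(1 + exceedances)/(1 + n_perm), which is exact-level under exchangeability
and never returns 0. Default n_perm is 4,999; the seed is recorded in every
result. The interaction test uses the nested-model statistic
F = ((RSS_reduced − RSS_full)/(m−1)) / (RSS_full/(n−2m)) with the reduced
model sharing one slope across orders, assessed by the same permutation
scheme. Permutation tests require the model to be built with
`from_matrices` (a tidy pair table alone cannot be relabeled at the taxon
level); fits and F statistics work from either construction.

The closed-form grouped OLS used inside the permutation loop is checked
against statsmodels OLS and hand-written normal equations in the test
suite; the two routes are kept independent.

## The simulator

`synthetic_data` evolves a genome of N single-copy genes on C chromosomes
down a phylogeny. Per branch of length t, event counts are Poisson with
mean rate × t, for three independent classes: intra-chromosomal events
(equal odds of a segment inversion with geometric length, mean
`inversion_mean_len`, or a single-gene transposition), single-gene
inter-chromosomal translocations, and gene losses. The focal gene of every
event is uniform over surviving genes, so larger chromosomes receive
proportionally more events. Clade-specific (rate_intra, rate_inter)
overrides apply on branches wholly inside one group's clade. Coordinates
are synthetic, evenly re-spaced after each branch; only order carries
information downstream.

Single-gene translocation (not segmental) is the default inter-chromosomal
move because the empirical end state this emulates is interleaved
single-gene placements after long divergence; segmental moves would create
block structure the statistic would read as recent fusion events.

Reference study conditions (`insect_like_config`): 100 taxa in five named
clades of 20 on a random ultrametric tree of height 1 (clade height 0.3),
1,300 genes on 12 chromosomes, rate_intra = 1,500, rate_inter = 25,
rate_loss = 30 events per unit branch length, inversion mean length 3, and
one clade ("Lepidoptera") at 3× the intra rate. These sit in the middle of
the regimes the pipeline targets — a hundred-odd chromosome-level genomes,
a BUSCO-scale shared gene set, translocation two orders of magnitude rarer
than reshuffling — and were fixed once, a priori. With ~450 intra events
per unit branch length per 1,300 genes, within-clade normalized GOC spans
roughly 0.9 down to 0.15, decaying approximately exponentially, and the
fast clade separates clearly; the acceptance script
(`scripts/acceptance.py`) recomputes the resulting F statistics, slopes and
p-values from scratch at these conditions.

What the simulator does *not* emulate: unequal genome/BUSCO-set sizes
across taxa, assembly fragmentation or misjoins, chromosome fusions and
fissions (chromosome number is constant up to total loss of a chromosome's
genes), duplications, rate variation along a branch, and any sequence-level
realism. Passing tests therefore establish the pipeline's statistical
behaviour under a clean rearrangement null, not robustness to assembly
artifacts; on real data, chromosome restriction and the single-copy filter
are the main defenses.

## Numerical and formatting conventions

* Coordinates are 1-based inclusive (BUSCO convention) internally; the
  windowed-profile writer emits 0-based half-open BED-like rows.
* Window profiles tile sequences with non-overlapping fixed-size bins
  (stride = window); genes belong to the bin containing their start.
* Matrix/TSV output uses 10 significant digits, making re-runs
  byte-identical; every CLI run writes a manifest with options and seed.
* Ordering ties, majority ties and taxon-name normalization are all
  resolved deterministically as described above, so identical inputs give
  identical outputs everywhere, including permutation null sequences under
  a fixed seed.

## Problem sizes used by the test suite and acceptance script

The suite exercises genomes of 40–200 genes on 2–6 chromosomes (where
brute-force oracles are affordable), permutation calibrations at
n_perm = 199 over 50–200 replicates, and model recovery at 500 pairs per
replicate; the acceptance script runs the full 100-taxon reference
conditions with n_perm = 999. These sizes were chosen so that every
stochastic check has enough replication to be stable under its stated
threshold while the whole suite stays fast.

## Known limitations

* The GOC neighbor rule scores window *membership*, not signed adjacency;
  two genomes differing only by local micro-inversions can score 1.0.
* Strict mode discards four genes per chromosome end per genome pair; on
  genomes with many tiny chromosomes, use relaxed mode.
* The cross-form F ranking inherits the response-scale caveat above.
* The permutation scheme assumes taxa are exchangeable under the null
  within the global relabeling; it does not condition on phylogenetic
  topology.
* `interaction_test` requires matrix-backed models (see above), a
  deliberate narrowing of the interface to keep the permutation unit
  well-defined.
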