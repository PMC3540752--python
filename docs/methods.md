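# Methods

This note documents the models, estimators, numerical choices and known
limitations of `biasnet`. It complements the README, which states the
headline formulas.

## Differential expression: the moderated Welch test

MAS5-style intensities are floored at 1 and log2-transformed; all
inference happens on the log2 scale. For each gene and sex the sample
variance has only n−1 degrees of freedom (n = 3 replicate pools by
default), so the classical Welch test is dominated by variance noise.
The moderated test assumes the per-gene true variances follow a
scaled-inverse-chi-square (equivalently inverse-gamma) prior with d0
degrees of freedom and scale s0², and replaces each per-sex sample
variance by the posterior mean

    s̃² = (d0·s0² + d·s²) / (d0 + d),  d = n − 1.

(d0, s0²) are estimated by a method of moments on z = log s²: under the
scaled-F model Var(z) = ψ′(d/2) + ψ′(d0/2) and
E(z) = log s0² + [ψ(d/2) − log(d/2)] − [ψ(d0/2) − log(d0/2)].
The trigamma equation is inverted for d0 by bisection (Brent); when the
observed spread of log variances does not exceed pure chi-square sampling
noise, d0 = ∞ (fully pooled). The digamma equation then yields s0².
Estimating s0² as the plain mean of sample variances would overstate the
prior scale by d0/(d0−2) and makes the test visibly conservative (null
Kolmogorov–Smirnov statistic around 0.05 at 2000 genes, versus 0.02–0.03
with the log-moment estimator); the plain mean is used only when the
caller fixes d0 explicitly, which preserves the exact d0 = 0 (classical
Welch) and d0 = ∞ (pooled) limits.

The statistic divides the mean difference by the shrunk standard error;
p-values use a t distribution with Satterthwaite degrees of freedom
computed on the shrunk variances, with per-group degrees of freedom
d0 + d (so d0 = 0 gives the classical Satterthwaite df and d0 = ∞ the
normal limit). Degenerate genes (zero variance in both groups and zero
mean difference) get t = 0, p = 1. Direction convention throughout:
positive statistic and positive log2 fold change mean male-biased.

Multiple testing is BH per condition over all genes on the array
(the FDR family matching per-condition reporting); bias classification
uses FDR < 0.1 by default, with the cutoff exposed for sensitivity
re-tests at stricter thresholds.

## Crosstalk

The null model must preserve each gene's degree, otherwise group-size and
hub effects masquerade as biology. Randomization is by attempted pairwise
swaps ((a,b),(c,d) → (a,d),(c,b)) with 10 attempts per link per
replicate; swaps creating self-loops or duplicate links are rejected
(rejection, not retry, so the attempt count is fixed and runs are
reproducible). Degree preservation is asserted on every replicate.
100 replicates by default. For each unordered label pair (self-pairs
included — within-group cohesion is itself the headline statistic) the
z-score uses the replicate mean and SD (ddof = 1); a two-sided normal
p accompanies an add-one empirical p. Pairs with a degenerate null
(SD = 0) report z = 0 and p = 1 when the observed count equals the null
mean (e.g. forced realizations such as K4) and are excluded from the BH
family otherwise. Z-chromosome stratification is done by composing
labels (male_Z, female_Z, ...) from the bias table and an optional
chromosome side table; the avian Z needs separate treatment because
incomplete dosage compensation inflates male expression of Z genes.

Link confidences ride along with swapped link slots during
randomization; crosstalk itself counts links and ignores weights.

## Bias vs connectivity

Spearman ρ is the Pearson correlation of mid-ranks; for n ≤ 9 the exact
permutation p is enumerated, otherwise the t approximation with n − 2 df
is used. The correlation deliberately uses the FDR itself (not a log
transform): rank-based ρ is invariant to monotone transforms, so the
choice only affects readability. Positive ρ means stronger bias (lower
FDR) associates with lower degree. Categories with fewer than 3 genes in
the network are skipped with a warning. The hub ranking uses mid-ranks on
both axes, with deterministic tie-breaking (smaller FDR, then gene id)
so output is stable across runs.

## Inparalog concordance

The sampling universe for the resampling null is all genes with
expression data, not only network genes — a pseudo-group is "a set of
genes the array could have produced", and the test asks whether real
duplicate groups are more bias-coherent than such sets. Draws are
without replacement within a group, independent across groups and
replicates. The empirical p is one-sided in the direction of the
observed deviation, with the add-one rule so p is never 0, and reported
with a +/− direction sign. Besides the four categories (all-male,
all-female, all-unbiased, mixed, plus the count of mixed groups
containing both sexes), the table reports `same_sex_bias` =
all_male + all_female, the single count the concordance question is
about.

## Module discovery

**Subnetwork construction.** For one sex, the seed set is that sex's
biased genes in the network; every other gene is tested with the
hypergeometric tail P(X ≥ k) where k = its links into the seed, n = its
degree, K = seed size, N = network size, Bonferroni-corrected by the
number of genes tested, recruited iff corrected p < 0.10. A gene of the
opposite bias whose links concentrate on the seed is recruited — by
design. The recruited set is monotone in the cutoff.

**MCL.** Transition matrix from link confidences with self-loops of
weight 1; iterate expansion (matrix squaring) and inflation (entrywise
power 3.5 then column renormalization) until the largest entry change is
below 1e-8 (cap 200 iterations, warning flag on non-convergence).
Pruning removes entries below 1e-5 *after* column normalization and is
followed by renormalization: pruning the raw inflated values instead
zeroes entire columns whose support exceeds ~30 entries (their
probabilities all fall below the threshold before rescaling) and
collapses the process to the identity. Clusters are read from attractors
(nodes with mass on their own row); attractor systems with overlapping
support merge, residual overlaps resolve to the cluster with the
lexicographically smallest member, and any unclaimed node follows its
strongest incoming flow. Output is deterministic and a partition.

**Shared-neighbor clustering ("mgclus-like").** The exact objective of
the MGclus program is unpublished, so the shared-neighbor principle is
implemented as documented agglomeration: node affinity = Jaccard index
of closed neighborhoods, cluster affinity = mean pairwise member
affinity (maintained exactly under merges by size-weighted averaging),
greedy merging while any affinity exceeds θ = 0.5, ties broken toward
the lexicographically smallest pair. All outputs are labeled
"mgclus-like". θ = 0.5 makes a pendant vertex (affinity 2/(s+1) to an
s-clique) fall out for s ≥ 4 while genuine near-cliques merge.

**GO significance.** A term is enriched in a cluster iff its
hypergeometric tail p < 0.05 (uncorrected) and ≥ 2 cluster genes carry
it; the background is the parental subnetwork. No per-term multiple-test
correction is applied because the randomization itself calibrates term
counts: the clustering-level z compares the observed average
enriched-term count per cluster with the distribution of that average
over 500 replicates of size-matched uniform draws from the subnetwork.
Only multi-gene clusters are evaluated (singletons cannot meet the
2-gene rule). A z above 2 corresponds to a one-sided normal tail below
0.05.

**Clustering comparison.** Jaccard matrices between the two clusterings'
clusters, by member genes and by enriched-term sets; UPGMA
(average-linkage, join height = distance/2, ties toward the smallest
label pair) over the union of clusters with distance 1 − Jaccard,
emitted as Newick. Heights are ultrametric by construction.

## Synthetic data

The generator emulates the *shape* of the real inputs at a desk-scale
size (2000 genes), chosen so the full pipeline and its randomizations run
in minutes on one CPU.

- **Network**: configuration model on power-law degrees
  (exponent 2.3, mean degree 8), then simplified. Degrees are drawn from
  a continuous truncated Pareto rounded to integers; the lower bound is
  solved so the mean matches the target, and the upper bound is the
  structural cutoff √(2m) of uncorrelated simple networks — without it,
  simplification at the largest hubs destroys both the mean and the tail.
  The expected planted-module links are discounted from the background
  target so the network-wide mean degree stays at the requested value.
  Link confidences are uniform on (0.25, 1], i.e. the network is already
  at the working confidence cutoff.
- **Planted modules** (3 × 30 genes: two male, one female) receive
  intra-module links with probability min(1, mult·mean_degree/(size−1)):
  the multiplier scales a member's expected within-module degree
  relative to the network-wide mean. At the default multiplier 8 the
  modules are near-cliques, the shape of pathway/complex neighborhoods
  in functional-coupling networks — and the only regime in which MCL at
  inflation 3.5 holds 30-gene modules together (an ER module at density
  0.3 fragments under that inflation).
- **Expression**: per gene, log2 baseline ~ N(8, 1) and variance ~
  inverse-gamma(shape 4, scale 0.75), i.e. mean within-gene variance
  0.25 (SD 0.5 on the log2 scale, typical for replicate pools of
  MAS5-normalized arrays). Biased genes gain +δ (default 2.5 log2 units)
  in their sex. 20% of genes are biased in total (module genes plus an
  even male/female background top-up), 3 replicate pools per sex.
- **Orthologs**: 30 groups (sizes 2–4). With probability 0.9 a group is
  drawn from a single true bias label (label chosen with probability
  equal to its frequency), otherwise uniformly.
- **Annotations**: one private term per planted module painted on 90% of
  its members, plus 37 background terms on random gene sets of 5–30.
- **Chromosome tags**: 10% of genes tagged Z uniformly at random; no
  dosage-compensation model (the tags exercise the stratification
  machinery, nothing more).

Everything is a pure function of (parameters, seed); emitted files
round-trip through the package readers.

**What the synthetic world does not show.** Passing tests demonstrate
the machinery is correct and calibrated, not that real tissues behave
this way. Known gaps: no probe-level noise or normalization artifacts;
no correlation between expression and connectivity (so the bias–degree
correlations on the default bundle hover near zero — the planted module
genes are in fact *high*-degree); no dosage-compensation physics behind
the Z tags; annotations give coherent terms only to planted modules, so
background clusters cannot be enriched. One geometric consequence worth
knowing: the planted modules make up ~26% of each sex's subnetwork, so
size-matched random draws from the subnetwork often hit enough
module-term genes to count as enriched, and the Table-5-style
clustering-level z on the default bundle sits near zero. The
discriminative power of the significance machinery is therefore
demonstrated on a painted-annotation configuration (z > 2) against a
uniform-annotation null (|z| < 2), both recomputed by the acceptance
script.

## Pipeline

The orchestrator runs per condition: DE → bias table → {crosstalk, hubs,
paralogs, modules}. A condition with fewer than 10 sex-biased genes
(e.g. an embryonic-brain-like null tissue) is excluded from crosstalk
and module discovery with an explicit notice — a handful of calls at
FDR 0.1 are expected false positives and cannot support group-level
statistics. The master seed derives per-condition, per-stage seeds via
`numpy.random.SeedSequence(master).spawn(...)` (all below 2^31), so any
stage can be reproduced in isolation from the manifest, which records
the package version, every parameter, and every derived seed. On stage
failure, partial outputs are removed and the error names the stage.

Problem sizes used by the test suite and the acceptance script (2000
genes, 30–100 randomization replicates for calibration sweeps, full
100/1000/500 replicates for the headline run) are the package's
documented desk-scale defaults.

## Known limitations

- The shared-neighbor clusterer is a principled stand-in for the
  unpublished MGclus objective, not a reimplementation of it.
- MCL cluster extraction from attractor overlap follows a fixed,
  documented convention; other MCL implementations may split overlaps
  differently.
- The crosstalk normal-approximation p is anticonservative when the null
  SD is estimated from few replicates; the empirical p is reported
  alongside and the calibration sweep bounds the practical consequence
  (≤ 10% of pairs beyond |z| = 2 under the null at 30 replicates).
- Real-data headline numbers (link counts per confidence cutoff, bias
  counts per tissue, printed correlations and cluster tables) depend on
  the original undeposited network and arrays and are out of scope.
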