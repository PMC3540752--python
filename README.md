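# biasnet

Network analysis of sex-biased gene expression.

Most studies of sexual dimorphism treat genes as independent units: a gene
is "male-biased" or "female-biased" by differential expression, and that is
where the analysis stops. `biasnet` implements the complementary
network-level questions for researchers working with functional-coupling
(FunCoup-style) gene networks and two-sex expression designs, such as the
chicken gonad/brain microarray panels that motivated it:

1. **Which genes are sex-biased?** A moderated Welch test per
   tissue/stage condition, built for the tiny replicate numbers of pooled
   designs (typically three pools per sex).
2. **Do sex-biased genes talk to each other?** Crosstalk: enrichment or
   depletion of links between bias groups (optionally stratified by
   Z chromosome vs autosome) against a degree-preserving randomization
   null.
3. **Are sex-biased genes hubs?** Spearman correlation of
   differential-expression FDR with node degree per bias class, and a
   rank-sum list of the most sex-biased hub genes.
4. **Do recent duplicates keep their bias?** Classification of inparalog
   groups by bias concordance with a resampling null.
5. **Which modules are sex-biased?** Per-sex subnetworks of biased genes
   plus hypergeometrically enriched neighbors, clustered with MCL and a
   shared-neighbor method, with GO-coherence significance against random
   modules and UPGMA-based clustering comparison.

A synthetic-data generator produces networks, expression matrices,
ortholog groups, chromosome tags and annotations with planted, fully
known structure, so every stage is testable without access to the
original (undeposited) data.

## The statistics in brief

**Moderated Welch test.** Within one condition, per gene *g* and sex
*s* ∈ {M, F} with *n_s* replicates, sample mean *x̄_gs* and variance
*s²_gs* on log2 intensities (floored at 1), each per-sex variance is
shrunk toward a pooled prior:

    s̃²_gs = (d0·s0s² + (n_s−1)·s²_gs) / (d0 + n_s−1)

    t_g = (x̄_gM − x̄_gF) / sqrt(s̃²_gM/n_M + s̃²_gF/n_F)

with two-sided p from a t distribution with Satterthwaite degrees of
freedom computed on the shrunk variances (per-group df d0 + n_s − 1).
The prior (d0, s0²) is fitted by a method of moments on log s²
(trigamma/digamma equations of the scaled-F model); d0 = 0 recovers the
classical Welch test, d0 → ∞ the fully pooled test. P-values are
Benjamini–Hochberg adjusted; a gene is male-biased if FDR < 0.1 and
log2FC > 0, female-biased if log2FC < 0, unbiased otherwise.

**Crosstalk.** For groups *A*, *B*, the observed between-group link count
*c_AB* is compared with its distribution over 100 degree-preserving edge
randomizations (pairwise swaps, 10 attempts per link, rejecting
self-loops and duplicates): z = (c_AB − μ_null)/σ_null, with a
normal-approximation p, an add-one empirical p, and BH FDR over all group
pairs. Self-pairs (within-group cohesion) are included.

**Hubs.** Per bias class, Spearman ρ between per-gene FDR and degree
(mid-ranks; exact permutation p for n ≤ 9, t approximation otherwise).
Hub ranking: rank genes by FDR ascending and by degree descending,
re-rank by the sum of both ranks; the top of the list is the most
sex-biased hub.

**Inparalog concordance.** Groups with ≥ 2 expressed members are
classified all-male / all-female / all-unbiased / mixed. Each group is
re-drawn 1000 times as a same-size uniform sample from the expression
dataset; one-sided add-one empirical p per category in the direction of
the observed deviation, with the headline count being groups whose
members share one sex bias.

**Modules.** Seed = biased genes of one sex; every other network gene is
recruited iff the hypergeometric tail P(X ≥ links-to-seed) with
Bonferroni correction is < 10%. The induced subnetwork is clustered with
MCL (inflation 3.5) and an agglomerative shared-neighbor method (merge
while closed-neighborhood Jaccard affinity > 0.5). Cluster GO coherence
(terms with tail p < 0.05 carried by ≥ 2 cluster genes) is z-scored
against 500 size-matched random gene draws from the subnetwork, and the
two clusterings are compared by gene/term Jaccard matrices and UPGMA
trees (Newick output).

## Worked example

Generate the default synthetic bundle (2000 genes, scale-free network,
three planted 30-gene modules, sex effect 2.5 log2 units) and run the
numbered analyses:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_crosstalk.py
python analysis/04_hubs.py
python analysis/05_paralogs.py
python analysis/06_modules.py
```

Selected output (seed 1):

```
condition gonad_adult: d0 = 7.64
  bias counts: {'male': 236, 'female': 209, 'unbiased': 1555}
  planted-bias recall at FDR < 0.1: 399/400 = 99.8%
```

The moderated test pools ~7.6 extra degrees of freedom per gene and
recovers essentially all planted biased genes at FDR < 0.1.

```
          male - male         observed   747 null   264.3  z   +38.9 (enriched)
        female - female       observed   419 null   112.4  z   +32.8 (enriched)
        female - male         observed    88 null   352.8  z   -15.7 (depleted)
```

Same-bias genes are far more interlinked than the degree-preserving null
expects, and male–female links are depleted — the planted sex-specific
modules seen through the crosstalk lens.

```
   same_sex_bias: observed   6  null   0.50 +- 0.67  p 0.001 +*
```

Six inparalog groups are uniformly sex-biased where chance predicts 0.5:
duplicates keep their bias (the generator planted 90% concordance).

```
planted-module recovery ARI (MCL): 0.934
planted-module recovery ARI (mgclus-like): 1.000
```

Both clusterers recover the planted modules from the per-sex
subnetworks.

The same pipeline is available as a CLI (`biasnet simulate|de|crosstalk|
hubs|paralogs|modules|run-all`) and as a single call,
`biasnet.pipeline.run_all(PipelineConfig(...))`, which writes all tables
plus a manifest that records every parameter and derived seed.

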