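"""Sex-biased network modules: subnetwork construction, clustering,
GO-enrichment significance, and clustering comparison.

For one condition and sex, the subnetwork contains the sex-biased genes
plus every other network gene whose links are significantly enriched in
connections to them (hypergeometric test with Bonferroni correction). The
subnetwork is partitioned into modules by two methods — Markov clustering
(MCL) and an agglomerative shared-neighbor ("mgclus-like") method — and
each clustering is scored by how many GO terms its modules enrich compared
to same-size random gene draws from the parental subnetwork. Clusterings
are compared by Jaccard overlap of module gene sets (and of enriched-term
sets), summarized as UPGMA trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import BiasTable
from .network_io import Network

logger = logging.getLogger(__name__)

#: Bonferroni-corrected p cutoff for recruiting strongly connected genes.
DEFAULT_BONFERRONI_CUTOFF = 0.10
#: MCL inflation: controls cluster granularity (higher = finer clusters).
DEFAULT_INFLATION = 3.5
#: Per-term uncorrected enrichment p cutoff (the random-module null
#: calibrates the resulting term counts, so no per-term correction).
GO_TERM_P_CUTOFF = 0.05
#: Random modules drawn per cluster size for the enrichment null.
DEFAULT_N_RAND_MODULES = 500
#: Stop threshold for the shared-neighbor agglomeration (Jaccard affinity).
DEFAULT_SN_THETA = 0.5

_MCL_PRUNE = 1e-5
_MCL_TOL = 1e-8
_MCL_MAX_ITER = 200


# ---------------------------------------------------------------------------
# hypergeometric tail


def z_tail_p(z: float) -> float:
    """One-sided standard-normal tail probability of a z-score.

    Used to interpret clustering-significance z-scores: a z above 2
    corresponds to p below 0.05.
    """
    return float(stats.norm.sf(z))


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    *N* population size, *K* marked in the population, *n* draws, *k*
    marked among the draws.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"impossible hypergeometric parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# subnetwork construction


@dataclass
class Subnetwork:
    """Seed (sex-biased) genes plus hypergeometrically recruited neighbors,
    with the induced links of the parent network."""

    parent: Network
    seed_genes: set[str]
    recruited_genes: set[str]
    graph_network: Network

    @property
    def genes(self) -> set[str]:
        return self.seed_genes | self.recruited_genes

    @property
    def n_links(self) -> int:
        return self.graph_network.n_links


def build_subnetwork(
    network: Network,
    bias: BiasTable,
    sex: str,
    bonferroni_cutoff: float = DEFAULT_BONFERRONI_CUTOFF,
) -> Subnetwork:
    """Subnetwork of one sex's biased genes and their enriched neighbors.

    Every non-seed network gene is tested with
    ``hypergeom_tail(k = links to seed, n = degree, K = seed genes in
    network, N = network genes)``; the p-value is Bonferroni-corrected by
    the number of genes tested and the gene is recruited iff the corrected
    p is below *bonferroni_cutoff*. Note a gene of the opposite bias can be
    recruited if its links concentrate on the seed set.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    seed = bias.genes_with(sex) & network.genes
    if not seed:
        raise ValueError(f"no {sex}-biased genes present in the network")
    all_genes = network.genes
    N = len(all_genes)
    K = len(seed)
    candidates = sorted(all_genes - seed)
    n_tests = len(candidates)
    recruited = set()
    for gene in candidates:
        nbrs = network.neighbors(gene)
        n = len(nbrs)
        if n == 0:
            continue
        k = len(nbrs & seed)
        if k == 0:
            continue  # tail p = 1, can never be recruited
        p = hypergeom_tail(k, n, K, N)
        if min(1.0, p * n_tests) < bonferroni_cutoff:
            recruited.add(gene)
    members = seed | recruited
    return Subnetwork(
        parent=network,
        seed_genes=seed,
        recruited_genes=recruited,
        graph_network=network.subgraph(members),
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass
class Clustering:
    """Disjoint gene clusters over a subnetwork.

    ``clusters`` holds the multi-gene clusters; ``singletons`` the genes
    that ended up alone. Cluster ids are assigned in order of each
    cluster's lexicographically smallest member, so output is deterministic.
    """

    clusters: list[frozenset[str]]
    singletons: set[str]
    method: str
    parameters: dict = field(default_factory=dict)
    converged: bool = True

    def labels(self) -> dict[str, int]:
        """Gene -> cluster index (singletons get their own indices after
        the multi-gene clusters)."""
        out = {}
        for i, cl in enumerate(self.clusters):
            for g in cl:
                out[g] = i
        for j, g in enumerate(sorted(self.singletons)):
            out[g] = len(self.clusters) + j
        return out

    def all_clusters(self) -> list[frozenset[str]]:
        return self.clusters + [frozenset([g]) for g in sorted(self.singletons)]


def _canonical_clusters(groups: list[set[str]]) -> tuple[list[frozenset[str]], set[str]]:
    multi = sorted(
        (frozenset(g) for g in groups if len(g) > 1), key=lambda c: min(c)
    )
    single = {next(iter(g)) for g in groups if len(g) == 1}
    return multi, single


def _adjacency(subnetwork: Subnetwork) -> tuple[list[str], np.ndarray]:
    nodes = sorted(subnetwork.genes)
    index = {g: i for i, g in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for a, b, c in subnetwork.graph_network.links():
        i, j = index[a], index[b]
        W[i, j] = W[j, i] = c
    return nodes, W


def mcl_cluster(
    subnetwork: Subnetwork, inflation: float = DEFAULT_INFLATION
) -> Clustering:
    """Markov clustering of a subnetwork.

    Builds a column-stochastic transition matrix from link confidences with
    self-loops of weight 1, then alternates expansion (matrix squaring) and
    inflation (entrywise power then column renormalization) with pruning of
    entries below 1e-5 until the largest entry change falls below 1e-8 (at
    most 200 iterations). Clusters are read from the attractors (nodes with
    mass on their own row); overlapping attractor systems are merged and a
    node appearing in several clusters is assigned to the one with the
    lowest id (smallest lexicographic member). Deterministic.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes, W = _adjacency(subnetwork)
    n = len(nodes)
    if n == 0:
        return Clustering([], set(), "mcl", {"inflation": inflation})
    A = W + np.eye(n)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(_MCL_MAX_ITER):
        E = M @ M
        np.power(E, inflation, out=E)
        colsums = E.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        E /= colsums
        # prune tiny *probabilities* (post-normalization), then renormalize
        E[E < _MCL_PRUNE] = 0.0
        colsums = E.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        E /= colsums
        if np.abs(E - M).max() < _MCL_TOL:
            M = E
            converged = True
            break
        M = E
    if not converged:
        logger.warning("MCL did not converge in %d iterations", _MCL_MAX_ITER)

    # attractors: rows with mass on the diagonal
    attractors = [i for i in range(n) if M[i, i] > 0]
    # merge attractor systems whose supported node sets overlap
    support = {i: set(np.flatnonzero(M[i] > 0)) for i in attractors}
    cluster_of: dict[int, int] = {}
    groups: list[set[int]] = []
    for i in attractors:
        merged_into = None
        for gi, grp in enumerate(groups):
            if support[i] & grp:
                if merged_into is None:
                    grp |= support[i]
                    merged_into = gi
                else:
                    groups[merged_into] |= grp
                    grp.clear()
        if merged_into is None:
            groups.append(set(support[i]))
    groups = [g for g in groups if g]
    # resolve residual overlaps / unassigned nodes
    name_groups = [{nodes[i] for i in g} for g in groups]
    name_groups.sort(key=lambda g: min(g))
    seen: set[str] = set()
    final: list[set[str]] = []
    for g in name_groups:
        g2 = g - seen  # overlap -> lowest cluster id keeps the node
        if g2:
            final.append(g2)
            seen |= g2
    for j, gene in enumerate(nodes):
        if gene not in seen:
            # no attractor claims this node: follow its strongest outflow
            i = int(np.argmax(M[:, j]))
            target = nodes[i]
            placed = False
            for g in final:
                if target in g:
                    g.add(gene)
                    placed = True
                    break
            if not placed:
                final.append({gene})
            seen.add(gene)
    multi, single = _canonical_clusters(final)
    return Clustering(
        clusters=multi,
        singletons=single,
        method="mcl",
        parameters={"inflation": inflation},
        converged=converged,
    )


def sharedneighbor_cluster(
    subnetwork: Subnetwork, theta: float = DEFAULT_SN_THETA
) -> Clustering:
    """Agglomerative shared-neighbor clustering (mgclus-like).

    The affinity of two nodes is the Jaccard index of their closed
    neighborhoods (neighbor sets including the nodes themselves), so nodes
    that are mutually linked *and* share many neighbors score high. Starting
    from singletons, the pair of clusters with the highest affinity — the
    mean pairwise member affinity — is merged greedily until no
    inter-cluster affinity exceeds *theta*. Ties break toward the
    lexicographically smallest cluster pair, making output deterministic.
    """
    nodes, W = _adjacency(subnetwork)
    n = len(nodes)
    if n == 0:
        return Clustering([], set(), "mgclus-like", {"theta": theta})
    adj = W > 0
    closed = adj | np.eye(n, dtype=bool)
    inter = (closed.astype(np.int32) @ closed.astype(np.int32).T).astype(float)
    sizes = closed.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    S = inter / union
    np.fill_diagonal(S, 0.0)

    members: list[set[int]] = [{i} for i in range(n)]
    size = np.ones(n)
    # pairwise cluster affinity = mean member-pair affinity; maintained via
    # size-weighted averaging under merges (exact for the mean)
    A = S.copy()
    active = list(range(n))
    min_name = [nodes[i] for i in range(n)]
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            i = active[ai]
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                a = A[i, j]
                if a <= theta:
                    continue
                pair_names = tuple(sorted((min_name[i], min_name[j])))
                key = (-a, pair_names)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        # merge j into i
        members[i] |= members[j]
        for k in active:
            if k in (i, j):
                continue
            A[i, k] = A[k, i] = (size[i] * A[i, k] + size[j] * A[j, k]) / (
                size[i] + size[j]
            )
        size[i] += size[j]
        min_name[i] = min(min_name[i], min_name[j])
        active.remove(j)
    groups = [{nodes[i] for i in members[c]} for c in active]
    multi, single = _canonical_clusters(groups)
    return Clustering(
        clusters=multi,
        singletons=single,
        method="mgclus-like",
        parameters={"theta": theta},
    )


# ---------------------------------------------------------------------------
# GO enrichment and clustering significance


def read_annotations(path) -> dict[str, set[str]]:
    """Read a flat gene -> GO-term annotation TSV (gene_id, term_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise ValueError(f"{path} must have columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        out.setdefault(g, set()).add(t)
    return out


def go_enrichment(
    cluster: set[str],
    background: set[str],
    annot: dict[str, set[str]],
    p_cutoff: float = GO_TERM_P_CUTOFF,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment of a cluster against a background.

    A term counts as enriched iff its tail p is below *p_cutoff* **and** at
    least two cluster genes carry it (a single annotated gene is never
    evidence of coherent function). Returns a DataFrame of enriched terms
    (term, k, K, p) sorted by p then term id.
    """
    cluster = set(cluster)
    if not cluster <= set(background):
        raise ValueError("cluster must be a subset of the background")
    N = len(background)
    n = len(cluster)
    term_counts_cluster: dict[str, int] = {}
    for g in cluster:
        for t in annot.get(g, ()):
            term_counts_cluster[t] = term_counts_cluster.get(t, 0) + 1
    term_counts_bg: dict[str, int] = {}
    for g in background:
        for t in annot.get(g, ()):
            term_counts_bg[t] = term_counts_bg.get(t, 0) + 1
    rows = []
    for term, k in term_counts_cluster.items():
        if k < 2:
            continue
        K = term_counts_bg[term]
        p = hypergeom_tail(k, n, K, N)
        if p < p_cutoff:
            rows.append({"term": term, "k": k, "K": K, "p": p})
    rows.sort(key=lambda r: (r["p"], r["term"]))
    return pd.DataFrame(rows, columns=["term", "k", "K", "p"])


@dataclass
class ClusteringSignificance:
    """GO-enrichment significance of a clustering vs random modules."""

    method: str
    n_clusters: int
    n_significant: int
    avg_enriched_terms: float
    random_avg_enriched_terms: float
    random_sd: float
    z: float


def clustering_significance(
    clustering: Clustering,
    subnetwork: Subnetwork,
    annot: dict[str, set[str]],
    n_rand: int = DEFAULT_N_RAND_MODULES,
    seed: int = 0,
) -> ClusteringSignificance:
    """Score a clustering's GO coherence against size-matched random modules.

    For each cluster, the number of enriched GO terms is compared to the
    distribution obtained by *n_rand* times drawing the same number of genes
    uniformly from the parental subnetwork. The clustering-level z-score
    contrasts the observed average enriched-term count per cluster with the
    distribution of that average over the random replicates. Deterministic
    given *seed*. Only multi-gene clusters are evaluated (singletons cannot
    satisfy the >= 2 annotated-gene rule).
    """
    if n_rand < 50:
        raise ValueError("n_rand must be >= 50")
    background = set(subnetwork.genes)
    bg_sorted = sorted(background)
    clusters = clustering.clusters
    if not clusters:
        raise ValueError("clustering has no multi-gene clusters to evaluate")
    for cl in clusters:
        if len(cl) > len(background):
            raise ValueError("cluster larger than its parental subnetwork")

    obs_counts = np.array(
        [len(go_enrichment(set(cl), background, annot)) for cl in clusters],
        dtype=float,
    )
    n_significant = int((obs_counts >= 1).sum())

    rng = np.random.default_rng(seed)
    sizes = sorted({len(cl) for cl in clusters})
    null_by_size: dict[int, np.ndarray] = {}
    for size in sizes:
        counts = np.empty(n_rand)
        for r in range(n_rand):
            draw = rng.choice(len(bg_sorted), size=size, replace=False)
            genes = {bg_sorted[i] for i in draw}
            counts[r] = len(go_enrichment(genes, background, annot))
        null_by_size[size] = counts
    # replicate-level averages across clusters (size-matched draws)
    null_avgs = np.mean(
        [null_by_size[len(cl)] for cl in clusters], axis=0
    )
    avg = float(obs_counts.mean())
    random_avg = float(null_avgs.mean())
    random_sd = float(null_avgs.std(ddof=1))
    z = (avg - random_avg) / random_sd if random_sd > 0 else float("nan")
    return ClusteringSignificance(
        method=clustering.method,
        n_clusters=len(clusters),
        n_significant=n_significant,
        avg_enriched_terms=avg,
        random_avg_enriched_terms=random_avg,
        random_sd=random_sd,
        z=float(z),
    )


# ---------------------------------------------------------------------------
# UPGMA and clustering comparison


def jaccard(a: set, b: set) -> float:
    """Intersection over union; 0 for two empty sets."""
    if not a and not b:
        return 0.0
    return len(set(a) & set(b)) / len(set(a) | set(b))


@dataclass
class UPGMATree:
    """UPGMA (average-linkage) tree over labeled items.

    ``merges`` lists ``(left, right, height)`` where heights are the
    ultrametric node heights (half the average pairwise distance).
    """

    newick: str
    merges: list[tuple[str, str, float]]


def upgma(dist: np.ndarray, labels: list[str]) -> UPGMATree:
    """UPGMA hierarchical clustering of a symmetric distance matrix.

    Repeatedly joins the pair of clusters at minimal average distance (ties
    broken toward the lexicographically smallest label pair), placing the
    join at height = distance / 2. Branch lengths in the Newick output are
    height differences, so leaf-to-node path lengths are ultrametric.
    """
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n == 1:
        return UPGMATree(newick=f"{labels[0]};", merges=[])
    D = dist.astype(float).copy()
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    newick_part = {i: labels[i] for i in range(n)}
    min_label = {i: labels[i] for i in range(n)}
    merges = []
    next_id = n
    Dmap = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i, j):
        return Dmap[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                i, j = active[a], active[b]
                d = get(i, j)
                pair = tuple(sorted((min_label[i], min_label[j])))
                key = (d, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        d = get(i, j)
        h = d / 2.0
        li, lj = newick_part[i], newick_part[j]
        bi = h - height[i]
        bj = h - height[j]
        newick_part[next_id] = f"({li}:{bi:.6g},{lj}:{bj:.6g})"
        merges.append((min_label[i], min_label[j], h))
        for k in active:
            if k in (i, j):
                continue
            dk = (size[i] * get(i, k) + size[j] * get(j, k)) / (size[i] + size[j])
            Dmap[(min(next_id, k), max(next_id, k))] = dk
        size[next_id] = size[i] + size[j]
        height[next_id] = h
        min_label[next_id] = min(min_label[i], min_label[j])
        active.remove(i)
        active.remove(j)
        active.append(next_id)
        next_id += 1
    root = active[0]
    return UPGMATree(newick=newick_part[root] + ";", merges=merges)


@dataclass
class ClusterComparison:
    """Pairwise overlap between two clusterings of the same subnetwork."""

    gene_jaccard: pd.DataFrame
    term_jaccard: pd.DataFrame
    gene_tree: UPGMATree
    term_tree: UPGMATree
    best_overlap: pd.DataFrame  # per cluster: best counterpart and fraction


def compare_clusterings(
    c1: Clustering,
    c2: Clustering,
    annot: dict[str, set[str]],
    background: set[str] | None = None,
) -> ClusterComparison:
    """Compare two clusterings by gene and enriched-term Jaccard overlap.

    Builds the Jaccard matrix between the clusterings' multi-gene clusters
    (by member genes and by enriched GO-term sets), UPGMA trees over the
    union of clusters using distance = 1 - Jaccard, and a per-cluster best
    counterpart table. The enrichment background defaults to the union of
    all clustered genes.
    """
    cl1, cl2 = c1.clusters, c2.clusters
    if not cl1 or not cl2:
        raise ValueError("both clusterings must have at least one cluster")
    if background is None:
        background = set().union(*cl1, *cl2)
    names1 = [f"{c1.method}_{i + 1}" for i in range(len(cl1))]
    names2 = [f"{c2.method}_{i + 1}" for i in range(len(cl2))]

    gj = np.array([[jaccard(a, b) for b in cl2] for a in cl1])
    terms1 = [set(go_enrichment(set(cl), background, annot)["term"]) for cl in cl1]
    terms2 = [set(go_enrichment(set(cl), background, annot)["term"]) for cl in cl2]
    tj = np.array([[jaccard(a, b) for b in terms2] for a in terms1])

    gene_jaccard = pd.DataFrame(gj, index=names1, columns=names2)
    term_jaccard = pd.DataFrame(tj, index=names1, columns=names2)

    def _combined_tree(sets1, sets2):
        all_sets = list(sets1) + list(sets2)
        labels = names1 + names2
        k = len(all_sets)
        D = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                D[i, j] = D[j, i] = 1.0 - jaccard(all_sets[i], all_sets[j])
        return upgma(D, labels)

    gene_tree = _combined_tree(cl1, cl2)
    term_tree = _combined_tree(terms1, terms2)

    rows = []
    for i, name in enumerate(names1):
        j = int(np.argmax(gj[i]))
        rows.append(
            {"cluster": name, "best_counterpart": names2[j], "overlap": gj[i, j]}
        )
    for j, name in enumerate(names2):
        i = int(np.argmax(gj[:, j]))
        rows.append(
            {"cluster": name, "best_counterpart": names1[i], "overlap": gj[i, j]}
        )
    return ClusterComparison(
        gene_jaccard=gene_jaccard,
        term_jaccard=term_jaccard,
        gene_tree=gene_tree,
        term_tree=term_tree,
        best_overlap=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# writers


def write_clustering(clustering: Clustering, bias: BiasTable | None, path) -> None:
    rows = []
    for i, cl in enumerate(clustering.all_clusters()):
        for g in sorted(cl):
            rows.append(
                {
                    "cluster_id": i + 1,
                    "gene_id": g,
                    "bias": (
                        bias.labels.get(g, "unknown") if bias is not None else "unknown"
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_significance(results: list[ClusteringSignificance], path) -> None:
    pd.DataFrame(
        [
            {
                "method": r.method,
                "clusters": r.n_clusters,
                "significant": r.n_significant,
                "avg_sig_terms": r.avg_enriched_terms,
                "random_avg_sig_terms": r.random_avg_enriched_terms,
                "z": r.z,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
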