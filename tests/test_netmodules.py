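import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from biasnet.diffexpr import BiasTable
from biasnet.netmodules import (
    DEFAULT_BONFERRONI_CUTOFF,
    DEFAULT_INFLATION,
    DEFAULT_N_RAND_MODULES,
    build_subnetwork,
    clustering_significance,
    compare_clusterings,
    go_enrichment,
    hypergeom_tail,
    jaccard,
    mcl_cluster,
    sharedneighbor_cluster,
    upgma,
)
from biasnet.network_io import network_from_links

from .conftest import clique_links, make_network, make_subnetwork


def _hypergeom_enum(k, n, K, N):
    """Exhaustive-enumeration oracle: sum of C(K,i)C(N-K,n-i)/C(N,n)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
    ) / total


def _bias(labels: dict) -> BiasTable:
    return BiasTable(
        labels=pd.Series(labels, name="bias"),
        condition=("gonad", "adult"),
        fdr_cutoff=0.1,
    )


class TestHypergeomTail:
    def test_boundary_values(self):
        assert hypergeom_tail(0, 3, 4, 10) == 1.0
        assert hypergeom_tail(5, 5, 5, 5) == 1.0

    def test_small_example_equals_enumeration(self):
        assert hypergeom_tail(3, 3, 4, 10) == pytest.approx(4 / 120, abs=1e-12)

    def test_impossible_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(4, 3, 2, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 2, 11, 10)

    def test_matches_enumeration_on_sample_of_tuples(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, n + 1))
            assert hypergeom_tail(k, n, K, N) == pytest.approx(
                _hypergeom_enum(k, n, K, N), abs=1e-12
            )


class TestBuildSubnetwork:
    def test_default_bonferroni_cutoff(self):
        assert DEFAULT_BONFERRONI_CUTOFF == 0.10

    def _net_with_seed_hub(self):
        # 8 male-biased genes forming a clique; "probe" links only to them;
        # "far" links only to unbiased background
        males = [f"m{i}" for i in range(8)]
        links = clique_links(males, 0.9)
        links += [("probe", m, 0.9) for m in males[:5]]
        bg = [f"u{i}" for i in range(30)]
        links += [(bg[i], bg[i + 1], 0.9) for i in range(29)]
        links += [("far", bg[0], 0.9), ("far", bg[1], 0.9)]
        labels = {m: "male" for m in males}
        labels.update({g: "unbiased" for g in bg})
        labels.update({"probe": "female", "far": "unbiased"})
        return make_network(links), _bias(labels)

    def test_enriched_neighbor_recruited_even_with_opposite_bias(self):
        net, bias = self._net_with_seed_hub()
        sub = build_subnetwork(net, bias, "male")
        assert "probe" in sub.recruited_genes  # female gene, links go to seed
        assert "far" not in sub.genes

    def test_gene_without_seed_links_never_recruited(self):
        net, bias = self._net_with_seed_hub()
        sub = build_subnetwork(net, bias, "male", bonferroni_cutoff=0.999)
        assert "far" not in sub.recruited_genes

    def test_recruited_set_monotone_in_cutoff(self):
        net, bias = self._net_with_seed_hub()
        prev: set = set()
        for cutoff in (0.001, 0.01, 0.1, 0.5, 0.999):
            sub = build_subnetwork(net, bias, "male", bonferroni_cutoff=cutoff)
            assert prev <= sub.recruited_genes
            prev = sub.recruited_genes

    def test_empty_seed_errors(self):
        net = make_network([("a", "b", 0.9)])
        with pytest.raises(ValueError):
            build_subnetwork(net, _bias({"a": "unbiased", "b": "unbiased"}), "male")


def _mcl_oracle(subnetwork, inflation=3.5):
    """Independent straightforward MCL transcription (matrix iteration),
    clusters read as connected components of the converged flow graph."""
    import networkx as nx

    nodes = sorted(subnetwork.genes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for a, b, c in subnetwork.graph_network.links():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = c
    M = W + np.eye(n)
    M = M / M.sum(0, keepdims=True)
    for _ in range(200):
        E = np.linalg.matrix_power(M, 2) ** inflation
        E = E / E.sum(0, keepdims=True)
        E[E < 1e-5] = 0.0
        s = E.sum(0, keepdims=True)
        s[s == 0] = 1.0
        E = E / s
        if np.abs(E - M).max() < 1e-8:
            M = E
            break
        M = E
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(M)):
        if i != j:
            g.add_edge(int(i), int(j))
    return {frozenset(nodes[i] for i in comp) for comp in nx.connected_components(g)}


class TestMCL:
    def test_default_inflation(self):
        assert DEFAULT_INFLATION == 3.5

    def test_disjoint_triangles_are_separate_clusters(self):
        sub = make_subnetwork(
            clique_links(list("abc"), 0.9) + clique_links(list("xyz"), 0.9)
        )
        clu = mcl_cluster(sub)
        assert set(clu.clusters) == {frozenset("abc"), frozenset("xyz")}
        assert clu.singletons == set()

    def test_two_cliques_with_bridge_match_oracle_iteration(self):
        links = clique_links(list("abcde"), 0.8) + clique_links(list("fghij"), 0.8)
        links.append(("e", "f", 0.8))
        sub = make_subnetwork(links)
        clu = mcl_cluster(sub)
        assert set(clu.clusters) == {frozenset("abcde"), frozenset("fghij")}
        assert set(clu.clusters) == _mcl_oracle(sub)

    def test_partition_and_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i:02d}" for i in range(20)]
        links = [
            (a, b, float(0.3 + 0.7 * rng.random()))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.25
        ]
        sub = make_subnetwork(links, extra_genes=nodes)
        clu = mcl_cluster(sub)
        # output is a partition of the subnetwork genes
        seen = set()
        for cl in clu.all_clusters():
            assert not (cl & seen)
            seen |= cl
        assert seen == sub.genes
        # relabeling nodes relabels clusters identically
        rename = {n: f"x{n}" for n in nodes}
        sub2 = make_subnetwork(
            [(rename[a], rename[b], c) for a, b, c in links],
            extra_genes=[rename[n] for n in nodes],
        )
        clu2 = mcl_cluster(sub2)
        mapped = {frozenset(rename[g] for g in cl) for cl in clu.all_clusters()}
        assert mapped == set(clu2.all_clusters())

    def test_invalid_inflation_rejected(self):
        sub = make_subnetwork(clique_links(list("abc")))
        with pytest.raises(ValueError):
            mcl_cluster(sub, inflation=1.0)


class TestSharedNeighborClustering:
    def test_disjoint_cliques_recovered_for_any_theta(self):
        links = clique_links(list("abcd"), 0.9) + clique_links(list("wxyz"), 0.9)
        for theta in (0.1, 0.5, 0.9):
            clu = sharedneighbor_cluster(make_subnetwork(links), theta=theta)
            assert set(clu.clusters) == {frozenset("abcd"), frozenset("wxyz")}

    def test_pendant_vertex_excluded_at_default_theta(self):
        """Closed-neighborhood Jaccard of a pendant and its clique anchor is
        2/(s+1), below 0.5 for cliques of size >= 4."""
        for s in (4, 6, 9):
            nodes = [f"c{i}" for i in range(s)]
            links = clique_links(nodes, 0.9) + [("pendant", nodes[0], 0.9)]
            clu = sharedneighbor_cluster(make_subnetwork(links), theta=0.5)
            assert frozenset(nodes) in set(clu.clusters)
            assert "pendant" in clu.singletons

    def test_planted_modules_recovered(self):
        from biasnet.synthetic_data import adjusted_rand_index

        rng = np.random.default_rng(7)
        links = []
        truth = {}
        for mi in range(3):
            nodes = [f"m{mi}_{i:02d}" for i in range(12)]
            for g in nodes:
                truth[g] = mi
            links += [
                (a, b, float(0.5 + 0.5 * rng.random()))
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.9
            ]
        all_nodes = sorted(truth)
        for _ in range(15):  # sparse inter-module noise
            a, b = rng.choice(len(all_nodes), 2, replace=False)
            if truth[all_nodes[a]] != truth[all_nodes[b]]:
                links.append((all_nodes[a], all_nodes[b], 0.6))
        clu = sharedneighbor_cluster(make_subnetwork(links, extra_genes=all_nodes))
        lab = clu.labels()
        ari = adjusted_rand_index(
            [truth[g] for g in all_nodes], [lab[g] for g in all_nodes]
        )
        assert ari >= 0.9


class TestGOEnrichment:
    def test_single_annotated_gene_never_enriched(self):
        background = {f"g{i}" for i in range(50)}
        annot = {"g0": {"T"}}
        out = go_enrichment({"g0", "g1", "g2"}, background, annot)
        assert out.empty

    def test_fully_annotated_cluster_strongly_enriched(self):
        background = {f"g{i}" for i in range(100)}
        cluster = {f"g{i}" for i in range(5)}
        annot = {g: {"T"} for g in cluster}
        out = go_enrichment(cluster, background, annot)
        assert list(out["term"]) == ["T"]
        assert out["p"].iloc[0] == pytest.approx(
            1 / math.comb(100, 5), rel=1e-9
        )

    def test_empty_annotation_gives_empty_result(self):
        out = go_enrichment({"a", "b"}, {"a", "b", "c"}, {})
        assert out.empty

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"a"}, {"b"}, {})


class TestClusteringSignificance:
    def test_default_replicates(self):
        assert DEFAULT_N_RAND_MODULES == 500

    def _painted_subnetwork(self, noise_annot=False, seed=0):
        rng = np.random.default_rng(seed)
        links, truth = [], {}
        for mi in range(3):
            nodes = [f"m{mi}_{i:02d}" for i in range(10)]
            for g in nodes:
                truth[g] = mi
            links += clique_links(nodes, 0.9)
        sub = make_subnetwork(links)
        genes = sorted(truth)
        if noise_annot:
            annot = {}
            for t in range(6):
                for i in rng.choice(len(genes), size=10, replace=False):
                    annot.setdefault(genes[i], set()).add(f"T{t}")
        else:
            annot = {g: {f"T{truth[g]}"} for g in genes}
        return sub, truth, annot

    def test_painted_module_annotation_gives_high_z(self):
        sub, truth, annot = self._painted_subnetwork()
        clu = mcl_cluster(sub)
        sig = clustering_significance(clu, sub, annot, n_rand=100, seed=1)
        assert sig.z > 2
        assert sig.n_significant == sig.n_clusters == 3

    def test_uniform_annotation_rarely_significant(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            sub, truth, annot = self._painted_subnetwork(noise_annot=True, seed=seed)
            clu = mcl_cluster(sub)
            sig = clustering_significance(clu, sub, annot, n_rand=100, seed=seed)
            if abs(sig.z) > 2:
                hits += 1
        assert hits <= n_seeds * 0.3

    def test_oversized_cluster_rejected(self):
        sub, _, annot = self._painted_subnetwork()
        from biasnet.netmodules import Clustering

        clu = Clustering(
            clusters=[frozenset(list(sub.genes) + ["ghost"])],
            singletons=set(),
            method="mcl",
        )
        with pytest.raises(ValueError):
            clustering_significance(clu, sub, annot, n_rand=60, seed=0)


class TestUPGMAAndComparison:
    def test_three_leaf_hand_computation(self):
        D = np.array(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]]
        )
        tree = upgma(D, ["c1", "c2", "c3"])
        assert tree.merges[0] == ("c1", "c2", pytest.approx(0.1))
        assert tree.merges[1][2] == pytest.approx(0.35)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(3)
        n = 7
        X = rng.random((n, 4))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        tree = upgma(D, [f"L{i}" for i in range(n)])
        Z = average(squareform(D, checks=False))
        mine = sorted(2 * h for _, _, h in tree.merges)
        ref = sorted(Z[:, 2])
        assert mine == pytest.approx(ref, rel=1e-10)

    def test_heights_nondecreasing_ultrametric(self):
        rng = np.random.default_rng(4)
        for seed in range(10):
            n = 8
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = upgma(D, [f"L{i}" for i in range(n)])
            heights = [h for _, _, h in tree.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_jaccard_basics(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)
        assert jaccard(set(), set()) == 0.0

    def test_identical_clusterings_full_overlap(self):
        from biasnet.netmodules import Clustering

        clusters = [frozenset("abc"), frozenset("def")]
        c1 = Clustering(clusters=clusters, singletons=set(), method="mcl")
        c2 = Clustering(clusters=clusters, singletons=set(), method="mgclus-like")
        annot = {g: {"T1"} for g in "abc"}
        annot.update({g: {"T2"} for g in "def"})
        cmp_ = compare_clusterings(c1, c2, annot)
        diag = np.diag(cmp_.gene_jaccard.to_numpy())
        assert diag == pytest.approx([1.0, 1.0])
        assert (cmp_.best_overlap["overlap"] == 1.0).all()
        assert cmp_.gene_tree.newick.endswith(";")
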