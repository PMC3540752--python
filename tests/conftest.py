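import itertools

import numpy as np
import pandas as pd
import pytest

from biasnet.diffexpr import ExpressionMatrix
from biasnet.netmodules import Subnetwork
from biasnet.network_io import Network, network_from_links


def make_network(links, extra_genes=()) -> Network:
    return network_from_links(links, extra_genes=extra_genes)


def make_subnetwork(links, extra_genes=()) -> Subnetwork:
    """Wrap an edge list as a Subnetwork whose seed set is all genes."""
    net = network_from_links(links, extra_genes=extra_genes)
    return Subnetwork(
        parent=net,
        seed_genes=net.genes,
        recruited_genes=set(),
        graph_network=net,
    )


def clique_links(genes, confidence=0.8):
    return [(a, b, confidence) for a, b in itertools.combinations(genes, 2)]


def expression_from_log2(log2_values, gene_ids, n_male, n_female,
                         tissue="gonad", stage="adult"):
    """Build an ExpressionMatrix from a genes x samples log2 array."""
    arr = np.exp2(np.asarray(log2_values, dtype=float))
    cols = [f"m{i}" for i in range(n_male)] + [f"f{i}" for i in range(n_female)]
    values = pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    meta = pd.DataFrame(
        {
            "sample": cols,
            "sex": ["male"] * n_male + ["female"] * n_female,
            "tissue": [tissue] * len(cols),
            "stage": [stage] * len(cols),
            "replicate": [str(i + 1) for i in range(n_male)]
            + [str(i + 1) for i in range(n_female)],
        }
    ).set_index("sample")
    return ExpressionMatrix(values=values, sample_meta=meta)


@pytest.fixture(scope="session")
def default_bundle():
    """The documented default synthetic bundle (seed 1), shared read-only."""
    from biasnet.synthetic_data import SimParams, simulate_bundle

    params = SimParams(seed=1)
    network, expr, groups, annot, truth = simulate_bundle(params)
    return {
        "params": params,
        "network": network,
        "expression": expr,
        "groups": groups,
        "annotations": annot,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_bias(default_bundle):
    from biasnet.diffexpr import classify_bias, moderated_welch

    de = moderated_welch(default_bundle["expression"], ("gonad", "adult"))
    return de, classify_bias(de)
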