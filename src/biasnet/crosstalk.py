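"""Crosstalk between gene groups under degree-preserving network randomization.

Crosstalk asks whether two gene sets (for example male-biased and
female-biased genes, optionally stratified by Z chromosome vs autosome)
are linked to each other more or less often than expected by chance. The
null model preserves every gene's degree exactly: links are repeatedly
swapped pairwise ((a,b),(c,d) -> (a,d),(c,b)), rejecting swaps that would
create a self-loop or duplicate link. The observed between-group link count
is compared to its distribution over many randomized networks, yielding a
z-score, a normal-approximation p-value, an empirical p-value, and a BH FDR
across all group pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import BiasTable, bh_fdr
from .network_io import Network, network_from_links

logger = logging.getLogger(__name__)

#: Number of randomized networks averaged over.
DEFAULT_N_RAND = 100
#: Attempted swaps per link in each randomization (burn-in length).
DEFAULT_SWAPS_PER_LINK = 10


def validate_partition(partition: dict[str, str], network: Network) -> None:
    """Check the strict partition contract: every labeled gene is in the
    network and carries exactly one label (guaranteed by dict keys)."""
    missing = set(partition) - network.genes
    if missing:
        raise ValueError(
            f"{len(missing)} labeled genes absent from network, "
            f"e.g. {sorted(missing)[:3]}"
        )


def compose_bias_partition(
    bias: BiasTable, chromosome_classes: dict[str, str] | None = None
) -> dict[str, str]:
    """Build a gene -> group-label partition from a bias table.

    Without chromosome classes the labels are the bias labels themselves.
    With classes, Z-linked genes get a ``_Z`` suffix (``male_Z`` etc.) so
    that the Z chromosome, which lacks complete dosage compensation in
    birds, is treated as a separate stratum.
    """
    out = {}
    for gene, label in bias.labels.items():
        if chromosome_classes is not None and chromosome_classes.get(gene) == "Z":
            out[gene] = f"{label}_Z"
        else:
            out[gene] = label
    return out


def _edges_to_arrays(network: Network):
    """Canonical node indexing and integer edge arrays for fast counting."""
    nodes = sorted(network.genes)
    index = {g: i for i, g in enumerate(nodes)}
    links = network.links()
    u = np.array([index[a] for a, b, _ in links], dtype=np.int64)
    v = np.array([index[b] for a, b, _ in links], dtype=np.int64)
    conf = np.array([c for _, _, c in links], dtype=float)
    return nodes, u, v, conf


def _swap_edges(
    u: np.ndarray, v: np.ndarray, rng: np.random.Generator, swaps_per_link: int
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-preserving pairwise edge swaps on integer edge arrays.

    Performs ``swaps_per_link * m`` attempted swaps; an attempt picks two
    distinct links and one of the two rewirings and commits it unless it
    would create a self-loop or a duplicate link.
    """
    m = len(u)
    if m < 2:
        return u.copy(), v.copy()
    uu, vv = u.copy(), v.copy()
    present = {(int(a), int(b)) if a < b else (int(b), int(a)) for a, b in zip(uu, vv)}
    n_attempts = swaps_per_link * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    orient = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        i, j = int(picks[t, 0]), int(picks[t, 1])
        if i == j:
            continue
        a, b = int(uu[i]), int(vv[i])
        c, d = int(uu[j]), int(vv[j])
        if orient[t]:
            c, d = d, c
        # proposed: (a,d) and (c,b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in present or e2 in present or e1 == e2:
            continue
        old1 = (a, b) if a < b else (b, a)
        old2 = (c, d) if c < d else (d, c)
        present.discard(old1)
        present.discard(old2)
        present.add(e1)
        present.add(e2)
        uu[i], vv[i] = e1
        uu[j], vv[j] = e2
    return uu, vv


def randomize_network(
    network: Network,
    seed: int,
    swaps_per_link: int = DEFAULT_SWAPS_PER_LINK,
) -> Network:
    """Return a degree-preserving randomization of *network*.

    The output has exactly the input's degree sequence (per gene) and the
    same gene set; link confidences ride along with the swapped link slots.
    Deterministic given *seed*.
    """
    if network.n_links < 2:
        raise ValueError("need at least 2 links to randomize")
    nodes, u, v, conf = _edges_to_arrays(network)
    rng = np.random.default_rng(seed)
    uu, vv = _swap_edges(u, v, rng, swaps_per_link)
    # degree preservation is structural; assert it anyway (cheap)
    n = len(nodes)
    deg_in = np.bincount(u, minlength=n) + np.bincount(v, minlength=n)
    deg_out = np.bincount(uu, minlength=n) + np.bincount(vv, minlength=n)
    assert (deg_in == deg_out).all(), "edge swap broke the degree sequence"
    links = [(nodes[a], nodes[b], c) for a, b, c in zip(uu, vv, conf)]
    out = network_from_links(links, cutoff=network.cutoff_applied, extra_genes=nodes)
    return out


def count_links(
    network: Network, label_a: str, label_b: str, partition: dict[str, str]
) -> int:
    """Number of links with one endpoint labeled *label_a* and the other
    *label_b*; for a self-pair each qualifying link is counted once."""
    labels = set(partition.values())
    for lab in (label_a, label_b):
        if lab not in labels:
            raise KeyError(f"label {lab!r} not present in partition")
    count = 0
    for a, b, _ in network.links():
        la, lb = partition.get(a), partition.get(b)
        if la is None or lb is None:
            continue
        if (la == label_a and lb == label_b) or (la == label_b and lb == label_a):
            count += 1
    return count


@dataclass
class CrosstalkResult:
    """Per group-pair crosstalk statistics.

    ``table`` rows are unordered label pairs (including self-pairs) with
    columns: observed, null_mean, null_sd, z, p_normal, p_empirical, fdr,
    sign. Pairs with a degenerate null (sd 0 but observed off the mean)
    have missing z and are excluded from the FDR family.
    """

    table: pd.DataFrame
    n_rand: int
    swaps_per_link: int
    seed: int


def _pair_counts(
    u: np.ndarray, v: np.ndarray, codes: np.ndarray, n_labels: int
) -> np.ndarray:
    """Counts per unordered label pair, indexed by lo * n_labels + hi.
    Edges with an unlabeled endpoint (code < 0) are ignored."""
    cu, cv = codes[u], codes[v]
    ok = (cu >= 0) & (cv >= 0)
    lo = np.minimum(cu[ok], cv[ok])
    hi = np.maximum(cu[ok], cv[ok])
    return np.bincount(lo * n_labels + hi, minlength=n_labels * n_labels)


def crosstalk(
    network: Network,
    partition: dict[str, str],
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
    swaps_per_link: int = DEFAULT_SWAPS_PER_LINK,
) -> CrosstalkResult:
    """Crosstalk z-scores for every unordered pair of group labels.

    For each pair, the observed link count is compared with its mean and
    standard deviation over *n_rand* degree-preserving randomizations:
    ``z = (observed - null_mean) / null_sd``; ``p_normal`` is the two-sided
    standard-normal tail, ``p_empirical`` the add-one two-sided empirical
    tail; BH FDR across all testable pairs. Genes in *partition* that are
    absent from the network are ignored with a warning.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    labels = sorted(set(partition.values()))
    if len(labels) < 2:
        raise ValueError("partition must define at least 2 group labels")
    extra = set(partition) - network.genes
    if extra:
        logger.warning(
            "%d labeled genes are not in the network and are ignored", len(extra)
        )

    nodes, u, v, _ = _edges_to_arrays(network)
    lab_index = {lab: i for i, lab in enumerate(labels)}
    codes = np.array([lab_index.get(partition.get(g, ""), -1) for g in nodes])
    L = len(labels)
    observed = _pair_counts(u, v, codes, L)

    rng = np.random.default_rng(seed)
    null = np.empty((n_rand, L * L), dtype=np.int64)
    n = len(nodes)
    deg = np.bincount(u, minlength=n) + np.bincount(v, minlength=n)
    for r in range(n_rand):
        uu, vv = _swap_edges(u, v, rng, swaps_per_link)
        deg_r = np.bincount(uu, minlength=n) + np.bincount(vv, minlength=n)
        assert (deg == deg_r).all(), "edge swap broke the degree sequence"
        null[r] = _pair_counts(uu, vv, codes, L)

    rows = []
    for i in range(L):
        for j in range(i, L):
            pid = i * L + j
            obs = int(observed[pid])
            ncounts = null[:, pid]
            mu = float(ncounts.mean())
            sd = float(ncounts.std(ddof=1))
            if sd == 0.0:
                z = 0.0 if obs == mu else np.nan
                p_norm = 1.0 if obs == mu else np.nan
            else:
                z = (obs - mu) / sd
                p_norm = 2.0 * stats.norm.sf(abs(z))
            p_emp = (1 + int((np.abs(ncounts - mu) >= abs(obs - mu)).sum())) / (
                n_rand + 1
            )
            rows.append(
                {
                    "label_a": labels[i],
                    "label_b": labels[j],
                    "observed": obs,
                    "null_mean": mu,
                    "null_sd": sd,
                    "z": z,
                    "p_normal": p_norm,
                    "p_empirical": p_emp,
                }
            )
    table = pd.DataFrame(rows)
    testable = table["z"].notna()
    fdr = np.full(len(table), np.nan)
    if testable.any():
        fdr[testable.to_numpy()] = bh_fdr(table.loc[testable, "p_normal"])
    table["fdr"] = fdr
    table["sign"] = np.where(
        table["z"] > 0, "enriched", np.where(table["z"] < 0, "depleted", "none")
    )
    return CrosstalkResult(
        table=table, n_rand=n_rand, swaps_per_link=swaps_per_link, seed=seed
    )


def write_crosstalk(result: CrosstalkResult, path) -> None:
    """Write the crosstalk table as TSV (also usable as a graph-viz edge
    table: label_a, label_b, z are the edge endpoints and weight)."""
    result.table.to_csv(path, sep="\t", index=False)
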