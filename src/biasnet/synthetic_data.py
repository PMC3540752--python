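"""Synthetic data with planted structure for every pipeline stage.

The generator emulates the statistical shape of the real inputs — a
scale-free functional-coupling network, a small-replicate two-sex
expression matrix on the MAS5 intensity scale, inparalog groups with
tunable bias concordance, chromosome-class tags, and flat GO annotations —
while recording the planted ground truth so recovery can be measured.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

from .diffexpr import ExpressionMatrix, write_expression
from .network_io import Network, network_from_links, write_network
from .paralogs import OrthologGroupSet, write_groups

#: log2-scale baseline intensity of a typical MAS5-normalized gene.
BASELINE_LOG2_MEAN = 8.0
BASELINE_LOG2_SD = 1.0


@dataclass
class SimParams:
    """Study conditions for the synthetic bundle.

    Defaults encode the conditions the analysis assumes: three replicate
    within-sex pools per condition, a scale-free network, a clear (but not
    extreme) sex-bias effect of 2.5 log2 units, three planted 30-gene
    modules, and 90% inparalog bias concordance.
    """

    n_genes: int = 2000
    degree_exponent: float = 2.3
    mean_degree: float = 8.0
    #: (size, bias label, intra multiplier): the multiplier scales each
    #: member's expected within-module degree relative to the network-wide
    #: mean degree (pairwise probability multiplier * mean_degree/(size-1),
    #: capped at 1), so modules emulate the dense, clique-like pathway and
    #: complex neighborhoods of functional-coupling networks.
    planted_modules: tuple[tuple[int, str, float], ...] = (
        (30, "male", 8.0),
        (30, "female", 8.0),
        (30, "male", 8.0),
    )
    effect_size_delta: float = 2.5  # log2 units
    reps_per_sex: int = 3
    variance_shape: float = 4.0  # inverse-gamma shape for per-gene variance
    variance_scale: float = 0.75  # inverse-gamma scale (mean var = 0.25)
    biased_fraction: float = 0.2
    ortholog_group_sizes: tuple[int, ...] = tuple([2] * 20 + [3] * 8 + [4] * 2)
    concordance: float = 0.9
    z_fraction: float = 0.1
    annotation_terms: int = 40
    annotation_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.reps_per_sex < 2:
            raise ValueError("n_genes must be positive and reps_per_sex >= 2")
        for frac in (self.concordance, self.biased_fraction, self.annotation_noise):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(s < 2 for s in self.ortholog_group_sizes):
            raise ValueError("ortholog groups need >= 2 members")


@dataclass
class GroundTruth:
    """Planted structure underlying a synthetic bundle."""

    bias: dict[str, str]  # gene -> {male, female, unbiased}
    modules: dict[str, int]  # gene -> planted module index (members only)
    module_labels: list[str]  # bias label per module
    chromosome: dict[str, str]  # gene -> {Z, autosome}
    concordant_groups: set[str] = field(default_factory=set)
    module_terms: dict[int, str] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.bias)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def _power_law_degrees(
    params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Power-law degrees from a truncated continuous Pareto, rounded.

    The density is proportional to ``x**(-gamma)`` on ``[xmin, k_max]``
    where the lower bound is solved so the distribution mean equals
    ``mean_degree`` and ``k_max ~ sqrt(2m)`` is the structural cutoff of
    uncorrelated simple networks.
    """
    gamma = params.degree_exponent
    if gamma <= 2:
        raise ValueError("degree_exponent must exceed 2 for a finite mean")
    # discount the expected planted-module links so the network-wide mean
    # degree stays at the requested value
    extra_links = sum(
        min(1.0, mult * params.mean_degree / (size - 1)) * size * (size - 1) / 2.0
        for size, _, mult in params.planted_modules
    )
    target_mean = max(1.5, params.mean_degree - 2.0 * extra_links / params.n_genes)
    # structural cutoff ~sqrt(2m) keeps the simplified graph close to the
    # drawn sequence (larger hubs would lose most stubs to multi-edges)
    k_max = float(
        min(params.n_genes - 1, np.sqrt(target_mean * params.n_genes))
    )
    a = gamma - 1.0  # tail exponent of the CCDF

    def mean_of(xmin: float) -> float:
        num = (a / (a - 1.0)) * (xmin ** (1.0 - a) - k_max ** (1.0 - a))
        den = xmin ** (-a) - k_max ** (-a)
        return num / den

    lo, hi = 1.0, k_max / 1.01
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_of(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    xmin = 0.5 * (lo + hi)
    # inverse-CDF draw from the truncated Pareto, rounded to integers
    u = rng.random(params.n_genes)
    x = (xmin ** (-a) - u * (xmin ** (-a) - k_max ** (-a))) ** (-1.0 / a)
    deg = np.maximum(1, np.rint(x)).astype(int)
    if deg.sum() % 2:  # configuration model needs an even stub count
        deg[int(np.argmin(deg))] += 1
    return deg


def simulate_network(params: SimParams) -> tuple[Network, GroundTruth]:
    """Configuration-model scale-free network with planted modules.

    Degrees follow a power law with the requested exponent; the multigraph
    is simplified (self-loops and multi-edges removed). Planted module
    members additionally link to each other with probability
    min(1, multiplier * mean_degree / (size - 1)): the multiplier scales a
    member's expected within-module degree relative to the network-wide
    mean, so modules at realistic multipliers are dense near-cliques (the
    shape of pathway and complex neighborhoods in functional-coupling
    networks) against the sparse background. Confidences are uniform in
    (0.25, 1]. Bias labels combine
    module labels with background biased genes up to ``biased_fraction``;
    a ``z_fraction`` of genes is tagged as Z-linked.
    """
    rng = np.random.default_rng(params.seed)
    genes = _gene_ids(params.n_genes)
    deg = _power_law_degrees(params, rng)
    mg = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(mg)  # collapses multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))

    edges = {(min(a, b), max(a, b)) for a, b in g.edges()}

    # plant modules on distinct randomly chosen genes
    module_sizes = [m[0] for m in params.planted_modules]
    total = sum(module_sizes)
    if total > params.n_genes:
        raise ValueError("planted modules larger than the gene universe")
    chosen = rng.choice(params.n_genes, size=total, replace=False)
    modules: dict[str, int] = {}
    module_labels: list[str] = []
    pos = 0
    for mi, (size, label, mult) in enumerate(params.planted_modules):
        idx = chosen[pos : pos + size]
        pos += size
        module_labels.append(label)
        for i in idx:
            modules[genes[i]] = mi
        p_intra = min(1.0, mult * params.mean_degree / (size - 1))
        for a_i in range(size):
            for b_i in range(a_i + 1, size):
                if rng.random() < p_intra:
                    a, b = int(idx[a_i]), int(idx[b_i])
                    edges.add((min(a, b), max(a, b)))

    confs = 0.25 + 0.75 * rng.random(len(edges))
    sorted_edges = sorted(edges)
    links = [
        (genes[a], genes[b], float(c)) for (a, b), c in zip(sorted_edges, confs)
    ]
    network = network_from_links(links, cutoff=0.25, extra_genes=genes)

    # bias labels: module genes take their module label; top up with
    # background biased genes (evenly male/female) to biased_fraction
    bias = {g_: "unbiased" for g_ in genes}
    for g_, mi in modules.items():
        bias[g_] = module_labels[mi]
    n_target = int(round(params.biased_fraction * params.n_genes))
    pool = [g_ for g_ in genes if g_ not in modules]
    n_extra = max(0, n_target - len(modules))
    extra = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
    for rank, i in enumerate(sorted(extra)):
        bias[pool[i]] = "male" if rank % 2 == 0 else "female"

    n_z = int(round(params.z_fraction * params.n_genes))
    z_idx = set(rng.choice(params.n_genes, size=n_z, replace=False).tolist())
    chromosome = {
        genes[i]: ("Z" if i in z_idx else "autosome") for i in range(params.n_genes)
    }
    truth = GroundTruth(
        bias=bias,
        modules=modules,
        module_labels=module_labels,
        chromosome=chromosome,
    )
    return network, truth


def simulate_expression(
    params: SimParams,
    truth: GroundTruth,
    tissue: str = "gonad",
    stage: str = "adult",
) -> ExpressionMatrix:
    """MAS5-like expression matrix with the planted sex effects.

    Per gene, a log2 baseline ~ Normal(8, 1) and a variance drawn from an
    inverse-gamma(shape, scale); male-biased genes gain +delta (log2 units)
    in male samples, female-biased genes +delta in female samples. Each sex
    gets ``reps_per_sex`` replicate pools; values are emitted as 2^log2.
    """
    rng = np.random.default_rng(params.seed + 1)
    genes = truth.genes()
    n = len(genes)
    baseline = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=n)
    variance = 1.0 / rng.gamma(
        params.variance_shape, 1.0 / params.variance_scale, size=n
    )
    sd = np.sqrt(variance)
    reps = params.reps_per_sex
    cols, data = [], []
    meta_rows = []
    for sex in ("male", "female"):
        shift = np.zeros(n)
        for i, g_ in enumerate(genes):
            lab = truth.bias[g_]
            if lab == sex:
                shift[i] = params.effect_size_delta
        for r in range(reps):
            noise = rng.normal(0.0, 1.0, size=n) * sd
            log2v = baseline + shift + noise
            name = f"{tissue}_{stage}_{sex}_{r + 1}"
            cols.append(name)
            data.append(np.exp2(log2v))
            meta_rows.append(
                {
                    "sample": name,
                    "sex": sex,
                    "tissue": tissue,
                    "stage": stage,
                    "replicate": str(r + 1),
                }
            )
    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(values=values, sample_meta=meta)


def simulate_orthologs(params: SimParams, truth: GroundTruth) -> OrthologGroupSet:
    """Inparalog groups with tunable bias concordance.

    With probability ``concordance`` a group is drawn entirely from genes
    sharing one true bias label (the label chosen with probability equal to
    its frequency); otherwise members are drawn independently from the
    whole universe. Groups never repeat a gene internally.
    """
    rng = np.random.default_rng(params.seed + 2)
    genes = np.array(truth.genes())
    labels = np.array([truth.bias[g] for g in genes])
    by_label = {
        lab: np.flatnonzero(labels == lab) for lab in ("male", "female", "unbiased")
    }
    groups: dict[str, tuple[str, ...]] = {}
    concordant: set[str] = set()
    for gi, size in enumerate(params.ortholog_group_sizes):
        gid = f"og{gi:03d}"
        if rng.random() < params.concordance:
            anchor = int(rng.integers(len(genes)))
            lab = labels[anchor]
            pool = by_label[lab]
            if len(pool) >= size:
                idx = rng.choice(pool, size=size, replace=False)
                groups[gid] = tuple(genes[i] for i in idx)
                concordant.add(gid)
                continue
        idx = rng.choice(len(genes), size=size, replace=False)
        groups[gid] = tuple(genes[i] for i in idx)
    truth.concordant_groups = concordant
    return OrthologGroupSet(groups=groups, provenance="synthetic")


def simulate_annotations(
    params: SimParams, truth: GroundTruth
) -> dict[str, set[str]]:
    """Flat GO-style annotations with module-private terms.

    Each planted module gets a private term painted on a fraction
    (1 - annotation_noise) of its members; the remaining terms annotate
    random gene sets (sizes uniform in [5, 30]) as background.
    """
    if params.annotation_terms < 1:
        raise ValueError("annotation_terms must be >= 1")
    rng = np.random.default_rng(params.seed + 3)
    genes = truth.genes()
    annot: dict[str, set[str]] = {}

    def paint(term: str, members):
        for g_ in members:
            annot.setdefault(g_, set()).add(term)

    n_modules = len(truth.module_labels)
    module_members: dict[int, list[str]] = {i: [] for i in range(n_modules)}
    for g_, mi in truth.modules.items():
        module_members[mi].append(g_)
    for mi in range(n_modules):
        term = f"GO:M{mi:04d}"
        members = sorted(module_members[mi])
        keep = max(2, int(round((1.0 - params.annotation_noise) * len(members))))
        idx = rng.choice(len(members), size=min(keep, len(members)), replace=False)
        paint(term, (members[i] for i in idx))
        truth.module_terms[mi] = term

    n_background = max(0, params.annotation_terms - n_modules)
    for t in range(n_background):
        term = f"GO:B{t:04d}"
        size = int(rng.integers(5, 31))
        idx = rng.choice(len(genes), size=size, replace=False)
        paint(term, (genes[i] for i in idx))
    return annot


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.size != b.size or a.size == 0:
        raise ValueError("labelings must be nonempty and equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(cont).sum()
    sum_a = comb(cont.sum(axis=1)).sum()
    sum_b = comb(cont.sum(axis=0)).sum()
    total = comb(a.size)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def module_recovery_ari(truth: GroundTruth, clusterings: dict) -> float:
    """Adjusted Rand index of planted-module recovery.

    *clusterings* maps a sex label to the Clustering of that sex's
    subnetwork. Evaluated jointly over all planted module genes present in
    their sex's clustering: the true label is the planted module id, the
    predicted label the (sex, cluster id) pair. Joint evaluation keeps the
    index well-defined even when one sex carries a single module.
    """
    true_labels, pred_labels = [], []
    for sex, clustering in clusterings.items():
        lab = clustering.labels()
        for g, mi in sorted(truth.modules.items()):
            if truth.module_labels[mi] == sex and g in lab:
                true_labels.append(mi)
                pred_labels.append(f"{sex}:{lab[g]}")
    if not true_labels:
        raise ValueError("no planted module genes present in the clusterings")
    return adjusted_rand_index(true_labels, pred_labels)


def simulate_bundle(params: SimParams):
    """Generate the full coherent input bundle.

    Returns ``(network, expression, groups, annotations, truth)``.
    """
    network, truth = simulate_network(params)
    expr = simulate_expression(params, truth)
    groups = simulate_orthologs(params, truth)
    annot = simulate_annotations(params, truth)
    return network, expr, groups, annot, truth


def emit_bundle(params: SimParams, outdir) -> dict[str, Path]:
    """Write the full input bundle (plus ground truth) to *outdir* as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, expr, groups, annot, truth = simulate_bundle(params)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "groups": outdir / "ortholog_groups.tsv",
        "chromosome": outdir / "chromosome_classes.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "ground_truth.tsv",
        "params": outdir / "sim_params.tsv",
    }
    write_network(network, paths["network"])
    write_expression(expr, paths["expression"], paths["sample_meta"])
    write_groups(groups, paths["groups"])
    pd.DataFrame(
        {"gene_id": sorted(truth.chromosome), "class": [truth.chromosome[g] for g in sorted(truth.chromosome)]}
    ).to_csv(paths["chromosome"], sep="\t", index=False)
    rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(annot)
        for t in sorted(annot[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        paths["annotations"], sep="\t", index=False
    )
    truth_rows = [
        {
            "gene_id": g,
            "true_bias": truth.bias[g],
            "module": truth.modules.get(g, -1),
            "chromosome": truth.chromosome[g],
        }
        for g in truth.genes()
    ]
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(
        [{"param": k, "value": str(v)} for k, v in asdict(params).items()]
    ).to_csv(paths["params"], sep="\t", index=False)
    return paths
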