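"""Sex-bias concordance of inparalog groups.

Inparalogs are genes that duplicated after the speciation event defining
an ortholog group (e.g. chicken genes that duplicated after the bird-mammal
split). Each group with at least two expressed members is classified by the
sex-bias labels of its members (all-male, all-female, all-unbiased, or
mixed), and the observed category counts are compared to a resampling null
in which each group is replaced by a same-size random draw from the whole
expression dataset. A link-sharing report for a duplicate pair quantifies
how much of each gene's network neighborhood is private (a signature of
subfunctionalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import BiasTable
from .network_io import Network

#: Number of resampling replicates for the concordance null.
DEFAULT_N_REP = 1000

CATEGORIES = ("all_male", "all_female", "all_unbiased", "mixed")


@dataclass
class OrthologGroupSet:
    """Inparalog groups filtered to members with expression data."""

    groups: dict[str, tuple[str, ...]]
    n_dropped: int = 0
    provenance: str = ""

    def sizes(self) -> list[int]:
        return [len(m) for m in self.groups.values()]


def load_groups(path, expression_genes: set[str]) -> OrthologGroupSet:
    """Load ortholog groups from a TSV of (group_id, gene_id) rows.

    Members without expression data are removed; groups left with fewer
    than two members are excluded and counted in ``n_dropped``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"ortholog group file {path} is empty")
    if not {"group_id", "gene_id"}.issubset(df.columns):
        raise ValueError(f"{path} must have columns group_id, gene_id")
    groups: dict[str, tuple[str, ...]] = {}
    n_dropped = 0
    for gid, sub in df.groupby("group_id", sort=True):
        members = tuple(g for g in sub["gene_id"] if g in expression_genes)
        if len(members) >= 2:
            groups[str(gid)] = members
        else:
            n_dropped += 1
    return OrthologGroupSet(groups=groups, n_dropped=n_dropped, provenance=str(path))


def write_groups(groups: OrthologGroupSet, path) -> None:
    rows = [
        {"group_id": gid, "gene_id": g}
        for gid in sorted(groups.groups)
        for g in groups.groups[gid]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _classify_one(member_labels: list[str]) -> str:
    s = set(member_labels)
    if s == {"male"}:
        return "all_male"
    if s == {"female"}:
        return "all_female"
    if s == {"unbiased"}:
        return "all_unbiased"
    return "mixed"


@dataclass
class GroupClassification:
    """Category counts of inparalog groups for one condition.

    ``mixed_mf`` counts the mixed groups containing at least one male- and
    one female-biased member (bias switching within a duplicate family).
    """

    counts: dict[str, int]
    mixed_mf: int
    per_group: dict[str, str] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return sum(self.counts.values())


def classify_groups(groups: OrthologGroupSet, bias: BiasTable) -> GroupClassification:
    """Classify every group by its members' bias labels."""
    labels = bias.labels
    counts = {c: 0 for c in CATEGORIES}
    mixed_mf = 0
    per_group = {}
    for gid, members in groups.groups.items():
        missing = [g for g in members if g not in labels.index]
        if missing:
            raise KeyError(
                f"group {gid}: gene {missing[0]!r} has no bias label"
            )
        mlabels = [labels[g] for g in members]
        cat = _classify_one(mlabels)
        counts[cat] += 1
        per_group[gid] = cat
        if cat == "mixed" and "male" in mlabels and "female" in mlabels:
            mixed_mf += 1
    return GroupClassification(counts=counts, mixed_mf=mixed_mf, per_group=per_group)


@dataclass
class ResampleNull:
    """Resampling null for group-category counts.

    One row per category (plus ``mixed_mf``): observed count, null mean/sd,
    one-sided add-one empirical p in the direction of the observed deviation,
    and the direction sign (+ above chance, - below).
    """

    table: pd.DataFrame
    n_rep: int
    seed: int


def resample_null(
    groups: OrthologGroupSet,
    bias: BiasTable,
    n_rep: int = DEFAULT_N_REP,
    seed: int = 0,
) -> ResampleNull:
    """Compare observed category counts to same-size random pseudo-groups.

    Each replicate redraws every group as a uniform without-replacement
    sample (of the same size) from all genes with expression data, then
    re-classifies and tallies. The empirical p for a category is one-sided
    in the direction of the observed deviation, with the add-one rule so it
    can never be 0. Deterministic given *seed*.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    universe = np.asarray(bias.labels.index)
    label_arr = bias.labels.to_numpy()
    sizes = groups.sizes()
    if sizes and max(sizes) > universe.size:
        raise ValueError("sampling universe smaller than the largest group")

    observed_cls = classify_groups(groups, bias)
    observed = dict(observed_cls.counts)
    observed["mixed_mf"] = observed_cls.mixed_mf
    # headline statistic: number of groups whose members share one sex bias
    observed["same_sex_bias"] = observed["all_male"] + observed["all_female"]

    rng = np.random.default_rng(seed)
    cats = list(CATEGORIES) + ["mixed_mf", "same_sex_bias"]
    null = np.zeros((n_rep, len(cats)), dtype=np.int64)
    for r in range(n_rep):
        tallies = {c: 0 for c in cats}
        for size in sizes:
            idx = rng.choice(universe.size, size=size, replace=False)
            mlabels = label_arr[idx].tolist()
            cat = _classify_one(mlabels)
            tallies[cat] += 1
            if cat == "mixed" and "male" in mlabels and "female" in mlabels:
                tallies["mixed_mf"] += 1
        tallies["same_sex_bias"] = tallies["all_male"] + tallies["all_female"]
        null[r] = [tallies[c] for c in cats]

    rows = []
    for k, cat in enumerate(cats):
        obs = observed[cat]
        col = null[:, k]
        mu = float(col.mean())
        sd = float(col.std(ddof=1))
        direction = "+" if obs > mu else "-"
        if direction == "+":
            p = (1 + int((col >= obs).sum())) / (n_rep + 1)
        else:
            p = (1 + int((col <= obs).sum())) / (n_rep + 1)
        rows.append(
            {
                "category": cat,
                "observed": obs,
                "null_mean": mu,
                "null_sd": sd,
                "p": p,
                "direction": direction,
            }
        )
    return ResampleNull(table=pd.DataFrame(rows), n_rep=n_rep, seed=seed)


@dataclass(frozen=True)
class SharedLinksReport:
    gene_a: str
    gene_b: str
    shared: int
    frac_a_not_shared: float
    frac_b_not_shared: float
    n_links_a: int
    n_links_b: int


def shared_links(
    network: Network, gene_a: str, gene_b: str, cutoff: float | None = None
) -> SharedLinksReport:
    """Link-sharing report for a duplicate pair.

    Neighbor sets are taken at the given confidence cutoff (defaulting to
    the network's own cutoff), excluding the partner gene itself. Reports
    the shared-neighbor count and the fraction of each gene's links that are
    private. Fractions are 0 for a gene with no links.
    """
    for g in (gene_a, gene_b):
        if g not in network.genes:
            raise KeyError(f"gene {g!r} not in network")
    na = network.neighbors(gene_a, cutoff) - {gene_b}
    nb = network.neighbors(gene_b, cutoff) - {gene_a}
    shared = len(na & nb)
    fa = (len(na) - shared) / len(na) if na else 0.0
    fb = (len(nb) - shared) / len(nb) if nb else 0.0
    return SharedLinksReport(
        gene_a=gene_a,
        gene_b=gene_b,
        shared=shared,
        frac_a_not_shared=fa,
        frac_b_not_shared=fb,
        n_links_a=len(na),
        n_links_b=len(nb),
    )


def write_resample_null(result: ResampleNull, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)
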