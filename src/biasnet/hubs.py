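"""Sex bias versus network connectivity: correlations and hub rankings.

Two complementary views: (1) Spearman rank correlation between the
differential-expression FDR and node degree within each bias category — a
positive correlation means stronger sex bias (smaller FDR) goes with fewer
network connections; (2) a rank-sum scoring that surfaces the genes that
are simultaneously strongly sex-biased and highly connected (sex-biased
hubs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import BIAS_LABELS, BiasTable, DEResult

logger = logging.getLogger(__name__)

#: Number of top-ranked sex-biased hubs reported.
DEFAULT_TOP_N = 20

#: Largest n for which the exact permutation p-value is computed.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class CorrelationResult:
    category: str
    rho: float
    p: float
    n: int


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns ``(rho, p)`` where rho is the Pearson correlation of the
    mid-ranks. The two-sided p-value comes from the t approximation with
    n - 2 df, except for n <= 9 where the exact permutation distribution
    is enumerated. Constant input leaves rho undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("constant input vector: Spearman rho undefined")
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, abs(rho))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(min(1.0, 2.0 * stats.t.sf(abs(t), n - 2)))
    return (float(rho), float(p))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, abs_rho: float) -> float:
    n = rx.size
    count = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        r = _pearson(rx, ry[list(perm)])
        if abs(r) >= abs_rho - 1e-12:
            count += 1
    return count / total


def bias_degree_correlation(
    de: DEResult,
    degree_table: dict[str, int],
    bias: BiasTable,
    categories=BIAS_LABELS,
) -> list[CorrelationResult]:
    """Spearman correlation of DE FDR vs degree per bias category.

    Restricted to each category's genes present in the network. Categories
    with fewer than 3 genes are skipped with a warning. A positive rho means
    stronger bias (lower FDR) associates with lower degree.
    """
    results = []
    fdr = de.table["fdr"]
    for category in categories:
        genes = sorted(bias.genes_with(category) & set(degree_table) & set(fdr.index))
        if len(genes) < 3:
            logger.warning(
                "category %r has %d genes in the network; skipped",
                category,
                len(genes),
            )
            continue
        x = fdr.loc[genes].to_numpy()
        y = np.array([degree_table[g] for g in genes], dtype=float)
        rho, p = spearman(x, y)
        results.append(CorrelationResult(category=category, rho=rho, p=p, n=len(genes)))
    return results


def rank_hubs(
    de: DEResult, degree_table: dict[str, int], top_n: int = DEFAULT_TOP_N
) -> pd.DataFrame:
    """Rank genes by the sum of a sex-bias rank and a connectivity rank.

    bias_rank ranks ascending FDR (rank 1 = most biased, mid-ranks for
    ties); degree_rank ranks descending degree (rank 1 = biggest hub); the
    final order is ascending rank_sum with ties broken by smaller FDR, then
    lexicographic gene id. The top genes are the most sex-biased hubs.
    Returns the top *top_n* rows with columns gene, fdr, degree, bias_rank,
    degree_rank, rank_sum, final_rank.
    """
    genes = sorted(set(de.table.index) & set(degree_table))
    if not genes:
        raise ValueError("no genes shared between DE table and degree table")
    fdr = de.table.loc[genes, "fdr"].to_numpy()
    deg = np.array([degree_table[g] for g in genes], dtype=float)
    bias_rank = stats.rankdata(fdr)
    degree_rank = stats.rankdata(-deg)
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "fdr": fdr,
            "degree": deg.astype(int),
            "bias_rank": bias_rank,
            "degree_rank": degree_rank,
            "rank_sum": bias_rank + degree_rank,
        }
    )
    out = out.sort_values(
        ["rank_sum", "fdr", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out.head(top_n)


def write_correlations(results: list[CorrelationResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)


def write_hubs(ranking: pd.DataFrame, path) -> None:
    ranking.to_csv(path, sep="\t", index=False)
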