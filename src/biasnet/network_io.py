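"""Read, validate, filter and summarize functional-coupling networks.

A network is an undirected simple weighted graph over gene identifiers.
Each link carries a confidence score in (0, 1] (the probability-like score
of a predicted functional coupling) and optionally an evidence category
(``metabolic``, ``signaling``, ``combined`` or ``total``). Gene identifiers
are opaque, case-sensitive strings and are never normalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Working confidence cutoff: a reasonable tradeoff between accuracy and
#: coverage for FunCoup-style confidence scores.
DEFAULT_CUTOFF = 0.25

LINK_CATEGORIES = ("metabolic", "signaling", "combined", "total")
CHROMOSOME_CLASSES = ("Z", "autosome", "unknown")


class NetworkFormatError(ValueError):
    """Raised when a network file is malformed."""


@dataclass
class Network:
    """Undirected simple graph of gene-gene functional couplings.

    Attributes
    ----------
    graph
        ``networkx.Graph`` whose nodes are gene ids (str) and whose edges
        carry a ``confidence`` float attribute.
    cutoff_applied
        The confidence cutoff that was applied when the network was built;
        every stored link has confidence strictly above this value.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    cutoff_applied: float = 0.0

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def links(self) -> list[tuple[str, str, float]]:
        """Links as ``(gene_a, gene_b, confidence)`` with ``gene_a < gene_b``,
        in canonical lexicographic order (reproducible across runs)."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, float(d["confidence"])))
        out.sort()
        return out

    def neighbors(self, gene: str, cutoff: float | None = None) -> set[str]:
        """Neighbor set of *gene*, optionally at a stricter confidence cutoff."""
        if gene not in self.graph:
            raise KeyError(f"gene {gene!r} not in network")
        if cutoff is None:
            return set(self.graph.neighbors(gene))
        return {
            v
            for v in self.graph.neighbors(gene)
            if self.graph[gene][v]["confidence"] > cutoff
        }

    def subgraph(self, genes) -> "Network":
        sub = Network(cutoff_applied=self.cutoff_applied)
        sub.graph = nx.Graph(self.graph.subgraph(genes))
        return sub


def network_from_links(
    links, cutoff: float = 0.0, extra_genes=()
) -> Network:
    """Build a :class:`Network` from an iterable of ``(a, b, confidence)``.

    Self-links are dropped with a warning; duplicate unordered pairs collapse
    keeping the maximum confidence. Links at or below *cutoff* are excluded.
    """
    net = Network(cutoff_applied=cutoff)
    g = net.graph
    for item in links:
        a, b, conf = item[0], item[1], float(item[2])
        if a == b:
            logger.warning("dropping self-link on gene %r", a)
            continue
        if conf <= cutoff:
            continue
        if g.has_edge(a, b):
            if conf > g[a][b]["confidence"]:
                g[a][b]["confidence"] = conf
        else:
            g.add_edge(a, b, confidence=conf)
    for gene in extra_genes:
        g.add_node(gene)
    return net


def read_network(
    path,
    cutoff: float = DEFAULT_CUTOFF,
    category: str | None = None,
) -> Network:
    """Read a network from a TSV edge list.

    The file must have a header line with columns ``gene_a``, ``gene_b``,
    ``confidence`` and optionally ``category``; ``#`` comment lines are
    allowed. Links with confidence strictly greater than *cutoff* (and, if
    *category* is given and a category column exists, matching it) are kept.
    Duplicate unordered pairs collapse to the maximum confidence; self-links
    are dropped with a logged warning.
    """
    if not 0.0 <= cutoff < 1.0:
        raise ValueError(f"cutoff must be in [0, 1), got {cutoff}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise NetworkFormatError(f"cannot parse network file {path}: {exc}") from exc
    required = {"gene_a", "gene_b", "confidence"}
    if not required.issubset(df.columns):
        raise NetworkFormatError(
            f"network file {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad = conf.isna() | (conf <= 0) | (conf > 1)
    if bad.any():
        # +2: 1 for the header line, 1 for 0- vs 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise NetworkFormatError(
            f"{path}: confidence outside (0, 1] (or unparseable) at line {line}"
        )
    if category is not None and "category" in df.columns:
        df = df[df["category"] == category]
    rows = zip(df["gene_a"].astype(str), df["gene_b"].astype(str), conf[df.index])
    return network_from_links(rows, cutoff=cutoff)


def write_network(network: Network, path) -> None:
    """Write a network as a canonical sorted TSV (lexicographic pair order)."""
    rows = network.links()
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
    out.to_csv(path, sep="\t", index=False)


def read_chromosome_classes(path) -> dict[str, str]:
    """Read an optional gene -> chromosome class side table.

    TSV with columns ``gene_id`` and ``class``; classes are one of
    ``Z``, ``autosome``, ``unknown``. Genes absent from the table default
    to ``unknown`` downstream.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "class"}.issubset(df.columns):
        raise NetworkFormatError(
            f"chromosome table {path} must have columns gene_id, class"
        )
    bad = ~df["class"].isin(CHROMOSOME_CLASSES)
    if bad.any():
        raise NetworkFormatError(
            f"unknown chromosome class {df['class'][bad].iloc[0]!r} in {path}"
        )
    return dict(zip(df["gene_id"], df["class"]))


def degrees(network: Network) -> dict[str, int]:
    """Node degree (number of incident links) for every gene in the network,
    including isolated genes with degree 0."""
    return {g: int(d) for g, d in network.graph.degree()}


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log10 frequency vs log10 degree."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def loglog_fit(degrees_values, frequencies) -> PowerLawFit:
    """Ordinary least squares of log10(frequency) on log10(degree).

    Exact power-law input ``f(k) = a * k**(-g)`` recovers slope ``-g`` to
    machine precision. Frequencies must be positive.
    """
    x = np.asarray(degrees_values, dtype=float)
    y = np.asarray(frequencies, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a log-log fit")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("degrees and frequencies must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=int(x.size),
    )


def degree_loglog_fit(degree_table: dict[str, int], n_bins: int = 12) -> PowerLawFit:
    """Power-law diagnostic of a degree distribution.

    Fits the tail of the distribution, from the modal degree upward (the
    sub-modal region of a finite simple network reflects finite-size
    effects, not the power law). Nonzero degrees are counted into
    logarithmically spaced bins, converted to a frequency density
    (count / bin width; every occupied bin carries frequency >= 1 before
    normalization), and log10 density is regressed on log10 degree by
    least squares. Logarithmic binning avoids the flattening bias that the
    sparse singleton tail of a heavy-tailed sample induces in a per-degree
    fit. A scale-free network shows an approximately linear relationship
    with slope near minus the degree exponent.
    """
    ks = np.array([k for k in degree_table.values() if k > 0], dtype=float)
    if ks.size == 0 or np.unique(ks).size < 3:
        raise ValueError(
            "degree distribution degenerate: need >= 3 distinct nonzero degrees"
        )
    vals, cnts = np.unique(ks, return_counts=True)
    mode = vals[int(np.argmax(cnts))]
    ks = ks[ks >= mode]
    if np.unique(ks).size < 3:
        raise ValueError("fewer than 3 distinct degrees above the mode: fit rejected")
    edges = np.unique(
        np.rint(np.geomspace(ks.min(), ks.max() + 1, n_bins + 1)).astype(int)
    )
    counts, _ = np.histogram(ks, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * np.maximum(edges[1:] - 1, edges[:-1]))
    occupied = counts >= 1
    if occupied.sum() < 3:
        raise ValueError("fewer than 3 occupied degree bins: fit rejected")
    return loglog_fit(centers[occupied], counts[occupied] / widths[occupied])
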