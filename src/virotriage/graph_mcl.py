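"""Similarity-graph construction and Markov clustering (MCL).

Query-subject pairs from an all-vs-all comparison become the edges of an
undirected graph weighted by -log10(E-value), capped at 200 (an E-value of
exactly 0 takes the cap). Markov clustering then alternates expansion
(matrix squaring, i.e. two-step random-walk flow) with inflation (entrywise
power followed by column renormalization, default inflation 10) on the
column-stochastic adjacency matrix until the flow decomposes; clusters are
the connected components of the limit matrix's nonzero structure.

The implementation is sparse (scipy CSC) with entry pruning, and exposes
the maximum column-sum deviation observed across all normalization steps
so stochasticity can be audited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .io_formats import AlignmentRecord

__all__ = [
    "MCLParams",
    "Clustering",
    "edge_weight",
    "build_graph",
    "mcl_cluster",
    "cluster_size_histogram",
]

logger = logging.getLogger(__name__)


def edge_weight(evalue: float, cap: float = 200.0) -> float:
    """-log10 of an E-value, clamped to [0, cap]; evalue 0 maps to the cap."""
    if evalue < 0:
        raise ValueError("evalue must be non-negative")
    if evalue == 0.0:
        return cap
    return min(max(-math.log10(evalue), 0.0), cap)


def build_graph(records: Iterable[AlignmentRecord], cap: float = 200.0) -> nx.Graph:
    """Undirected similarity graph from alignment records.

    Every query and subject id becomes a node. Each qacc != sacc pair
    contributes one edge weighted by ``edge_weight``; when the two
    directions (or repeated pairs) disagree, the maximum weight is kept.
    Self-alignments contribute the node only.
    """
    g = nx.Graph()
    for rec in records:
        g.add_node(rec.qacc)
        g.add_node(rec.sacc)
        if rec.qacc == rec.sacc:
            continue
        w = edge_weight(rec.evalue, cap)
        if g.has_edge(rec.qacc, rec.sacc):
            if w > g.edges[rec.qacc, rec.sacc]["weight"]:
                g.edges[rec.qacc, rec.sacc]["weight"] = w
        else:
            g.add_edge(rec.qacc, rec.sacc, weight=w)
    return g


@dataclass(frozen=True)
class MCLParams:
    inflation: float = 10.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_eps: float = 1e-8
    self_loop: str = "max-incident-weight"

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if min(self.prune_threshold, self.max_iterations, self.convergence_eps) <= 0:
            raise ValueError("prune_threshold, max_iterations, convergence_eps must be positive")


@dataclass(frozen=True)
class Clustering:
    """A partition of node ids with its size statistics."""

    clusters: tuple[frozenset[str], ...]
    converged: bool = True
    iterations: int = 0
    max_column_dev: float = 0.0  # worst column-sum deviation from 1 seen

    @property
    def sizes(self) -> list[int]:
        return sorted(len(c) for c in self.clusters)

    @property
    def singleton_count(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)

    @property
    def n_nodes(self) -> int:
        return sum(len(c) for c in self.clusters)

    def labels(self) -> dict[str, int]:
        """Node -> cluster index, clusters ordered by smallest member id."""
        ordered = sorted(self.clusters, key=lambda c: min(c))
        return {node: i for i, cluster in enumerate(ordered) for node in cluster}


def _normalize_columns(m: sparse.csc_matrix) -> tuple[sparse.csc_matrix, float]:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    d = sparse.diags(1.0 / sums, format="csc")
    out = (m @ d).tocsc()
    dev = float(np.abs(np.asarray(out.sum(axis=0)).ravel() - 1.0).max()) if out.nnz else 0.0
    return out, dev


def mcl_cluster(graph: nx.Graph, params: MCLParams | None = None) -> Clustering:
    """Markov clustering of a weighted undirected graph.

    Adds one self-loop per node (at its maximum incident edge weight;
    isolated nodes get weight 1), column-normalizes, then iterates
    expansion -> inflation -> prune -> renormalize until the maximum
    entrywise change falls below ``convergence_eps`` or ``max_iterations``
    is reached (the latter returns the current clustering with a warning).
    Clusters are the connected components of the limit matrix's nonzero
    structure, which yields a deterministic partition even when attractor
    systems overlap.
    """
    params = params or MCLParams()
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return Clustering(clusters=())
    idx = {node: i for i, node in enumerate(nodes)}

    m = sparse.lil_matrix((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    m = m.tocsc()
    # self-loops: max incident weight, or 1 for isolated nodes
    if params.self_loop != "max-incident-weight":
        raise ValueError(f"unknown self_loop rule {params.self_loop!r}")
    col_max = np.zeros(n)
    if m.nnz:
        col_max = np.asarray(abs(m).max(axis=0).todense()).ravel()
    loops = np.where(col_max > 0.0, col_max, 1.0)
    m = (m + sparse.diags(loops, format="csc")).tocsc()

    m, dev = _normalize_columns(m)
    max_dev = dev
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev = m.copy()
        # expansion: matrix power
        expanded = m
        for _ in range(params.expansion - 1):
            expanded = (expanded @ m).tocsc()
        # inflation: entrywise power, renormalize
        inflated = expanded.copy()
        inflated.data = np.power(inflated.data, params.inflation)
        m, dev = _normalize_columns(inflated)
        max_dev = max(max_dev, dev)
        # prune tiny entries, renormalize
        m.data[m.data < params.prune_threshold] = 0.0
        m.eliminate_zeros()
        m, dev = _normalize_columns(m)
        max_dev = max(max_dev, dev)
        change = float(abs(m - prev).max()) if (m - prev).nnz else 0.0
        if change < params.convergence_eps:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge within %d iterations; returning current clustering",
            params.max_iterations,
        )

    structure = m + m.T
    n_comp, labels = connected_components(structure, directed=False)
    groups: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        groups.setdefault(int(lab), set()).add(node)
    clusters = tuple(
        frozenset(c) for c in sorted(groups.values(), key=lambda c: min(c))
    )
    return Clustering(
        clusters=clusters,
        converged=converged,
        iterations=iterations,
        max_column_dev=max_dev,
    )


def cluster_size_histogram(clustering: Clustering) -> dict:
    """Cluster counts per size, plus the singleton count and fraction."""
    hist: dict[int, int] = {}
    for c in clustering.clusters:
        hist[len(c)] = hist.get(len(c), 0) + 1
    n_clusters = len(clustering.clusters)
    singletons = clustering.singleton_count
    return {
        "histogram": dict(sorted(hist.items())),
        "singleton_count": singletons,
        "singleton_fraction": singletons / n_clusters if n_clusters else 0.0,
    }
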