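"""Interaction-network clustering and term enrichment.

Markov clustering (MCL) partitions a weighted protein-interaction graph by
alternating expansion (matrix power; random-walk flow spreads) and
inflation (elementwise power + column renormalization; strong flow is
rewarded) on the column-stochastic transition matrix until the matrix
stops changing.  Attractor rows of the limit matrix define the clusters.

Term enrichment of a cluster against a GMT-style annotation is the exact
upper-tail hypergeometric test, BH-corrected across terms — the generic
core of the gene-ontology enrichment stages that interaction studies
usually delegate to external services.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .design_io import ValidationError
from .quantitation import bh_adjust

__all__ = ["TermEnrichment", "mcl_cluster", "term_enrichment"]


@dataclass(frozen=True)
class TermEnrichment:
    term_id: str
    term_size: int
    overlap: int
    universe_size: int
    cluster_size: int
    p_value: float
    q_value: float


def _mcl_matrix(
    m: np.ndarray,
    inflation: float,
    expansion: int,
    prune_below: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Run the MCL iteration to convergence on a column-stochastic matrix."""

    def normalize(a: np.ndarray) -> np.ndarray:
        colsum = a.sum(axis=0)
        colsum[colsum == 0] = 1.0
        return a / colsum

    m = normalize(m)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = normalize(m)
        m = m**inflation
        m[m < prune_below] = 0.0
        m = normalize(m)
        if np.abs(m - prev).max() < tol:
            break
    return m


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 100,
    self_loop: str | float = "max",
) -> list[frozenset[str]]:
    """Markov clustering of a weighted undirected graph.

    Self-loops are added internally (weight = maximum incident edge
    weight by default, or a fixed number) before column normalization.
    Every node lands in exactly one cluster: a node attracted to several
    attractors goes with its highest-flow attractor, ties broken by
    lexicographic node id; attractors connected through each other's rows
    (attractor systems) form a single cluster.
    """
    if inflation <= 0:
        raise ValidationError("inflation must be positive")
    if graph.number_of_nodes() == 0:
        raise ValidationError("graph has no nodes")
    nodes = sorted(graph.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValidationError("edge weights must be positive")
        if a == b:
            continue  # input self-loops are replaced by our own
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    for i in range(n):
        if self_loop == "max":
            incident = m[:, i].max()
            m[i, i] = incident if incident > 0 else 1.0
        else:
            m[i, i] = float(self_loop)

    limit = _mcl_matrix(m, inflation, expansion, prune_below, tol, max_iter)

    # attractors: nodes with positive mass on their own row
    attractors = [i for i in range(n) if limit[i, i] > prune_below]
    if not attractors:  # safeguard for non-converged edge cases
        attractors = list(range(n))

    # attractor systems: attractors sharing flow merge into one cluster
    asys = nx.Graph()
    asys.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (limit[i, j] > prune_below or limit[j, i] > prune_below):
                asys.add_edge(i, j)
    system_of: dict[int, int] = {}
    for comp in nx.connected_components(asys):
        rep = min(comp)
        for i in comp:
            system_of[i] = rep

    clusters: dict[int, set[str]] = {}
    for j in range(n):
        cands = [i for i in attractors if limit[i, j] > prune_below]
        if j in attractors:
            chosen = j
        elif cands:
            # highest flow wins; ties broken by lexicographic node id
            best = max(limit[i, j] for i in cands)
            chosen = min(
                (i for i in cands if np.isclose(limit[i, j], best)),
                key=lambda i: nodes[i],
            )
        else:
            chosen = j  # orphan (fully pruned); keep as singleton seed
            system_of.setdefault(j, j)
        clusters.setdefault(system_of.get(chosen, chosen), set()).add(nodes[j])
    return sorted(
        (frozenset(c) for c in clusters.values()), key=lambda c: sorted(c)
    )


def term_enrichment(
    cluster: set[str] | frozenset[str],
    annotations: Mapping[str, set[str]],
    universe: set[str] | frozenset[str],
) -> list[TermEnrichment]:
    """Exact hypergeometric over-representation of each term in a cluster.

    p = P(overlap >= observed) drawing ``|cluster|`` proteins from the
    universe containing ``|term in universe|`` annotated ones; q is BH over
    all terms.  Zero-overlap terms are reported, not skipped.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not set(cluster) <= set(universe):
        raise ValidationError("cluster is not contained in universe")
    m_univ = len(universe)
    n_clust = len(cluster)
    rows = []
    for term_id in sorted(annotations):
        members = annotations[term_id] & set(universe)
        k = len(set(cluster) & members)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(members), n_clust))
        rows.append((term_id, len(members), k, min(p, 1.0)))
    qs = bh_adjust([r[3] for r in rows]) if rows else []
    return [
        TermEnrichment(
            term_id=tid,
            term_size=tsize,
            overlap=k,
            universe_size=m_univ,
            cluster_size=n_clust,
            p_value=p,
            q_value=float(q),
        )
        for (tid, tsize, k, p), q in zip(rows, qs)
    ]
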