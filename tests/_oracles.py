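"""Independent oracles shared by the test suite.

Each oracle recomputes a quantity by a route independent of the package's
implementation: exact rational enumeration for hypergeometric tails, and a
separately written dense matrix iteration for Markov clustering.
"""

import math
from fractions import Fraction

import networkx as nx
import numpy as np


def exact_upper_tail(a: int, row_bait: int, c: int, row_ctrl: int) -> Fraction:
    """P(X >= a) for the hypergeometric distribution at margins
    (row_bait, row_ctrl, k = a + c), summed with exact integer arithmetic."""
    k = a + c
    hi = min(row_bait, k)
    total = math.comb(row_bait + row_ctrl, k)
    if total == 0:
        return Fraction(1)
    num = sum(
        math.comb(row_bait, x) * math.comb(row_ctrl, k - x) for x in range(a, hi + 1)
    )
    return Fraction(num, total)


def mcl_oracle(graph: nx.Graph, inflation=2.0, expansion=2, max_iter=200):
    """Step-by-step MCL iteration, written independently of the package:
    max-incident self-loops, column normalization, expansion by repeated
    matrix multiplication, elementwise inflation, pruning at 1e-5;
    clusters read off as connected components of the limit-matrix support
    restricted to attractor rows."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        w = float(d.get("weight", 1.0))
        a[nodes.index(u), nodes.index(v)] = w
        a[nodes.index(v), nodes.index(u)] = w
    for i in range(n):
        a[i, i] = a[:, i].max() if a[:, i].max() > 0 else 1.0
    m = a / a.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m.copy()
        exp = m
        for _ in range(expansion - 1):
            exp = exp @ m
        m = exp**inflation
        m[m < 1e-5] = 0.0
        m = m / m.sum(axis=0, keepdims=True)
        if np.abs(m - prev).max() < 1e-6:
            break
    attractors = [i for i in range(n) if m[i, i] > 1e-5]
    support = nx.Graph()
    support.add_nodes_from(range(n))
    for i in attractors:
        for j in range(n):
            if m[i, j] > 1e-5:
                support.add_edge(i, j)
    return sorted(
        (frozenset(nodes[i] for i in comp) for comp in nx.connected_components(support)),
        key=lambda c: sorted(c),
    )
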