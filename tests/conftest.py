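"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from barcodegap.distance import DistanceMatrix


# ---------------------------------------------------------------------------
# independent K2P oracle: explicit per-site classification, formula inline
# ---------------------------------------------------------------------------

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def k2p_oracle(seq1: str, seq2: str):
    """Brute-force K2P: returns (P, Q, n, d) with d=None when saturated."""
    n = ts = tv = 0
    for a, b in zip(seq1, seq2):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        both_purine = a in PURINES and b in PURINES
        both_pyrimidine = a in PYRIMIDINES and b in PYRIMIDINES
        if both_purine or both_pyrimidine:
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return P, Q, n, None
    return P, Q, n, -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


# ---------------------------------------------------------------------------
# random additive matrices from networkx trees (oracle independent of phylo)
# ---------------------------------------------------------------------------


def random_additive(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree -> (DistanceMatrix, set of true bipartitions).

    Built as a networkx graph: start from a 3-leaf star and attach each
    further leaf to a uniformly chosen edge. Distances are weighted shortest
    paths, so the returned matrix is exactly additive.
    """
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    g = nx.Graph()
    centre = "I0"
    for leaf in labels[:3]:
        g.add_edge(centre, leaf, weight=float(rng.uniform(0.01, 0.2)))
    next_internal = 1
    for leaf in labels[3:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"I{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.01, 0.2)))

    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    values = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        values[i, j] = values[j, i] = dist[labels[i]][labels[j]]

    splits = set()
    anchor = min(labels)
    for u, v in list(g.edges()):
        if u.startswith("I") and v.startswith("I"):
            h = g.copy()
            h.remove_edge(u, v)
            side = {x for x in nx.node_connected_component(h, u) if x in labels}
            if 2 <= len(side) <= n_leaves - 2:
                if anchor in side:
                    side = set(labels) - side
                splits.add(frozenset(side))
    matrix = DistanceMatrix(
        labels, values, np.zeros((n_leaves, n_leaves), dtype=bool)
    )
    return matrix, splits


def enumerate_topologies(labels):
    """All unrooted binary topologies on the labels, as bipartition sets.

    Yields (splits, edges, nodes) where edges is a list of frozenset node
    pairs on an explicit graph, for least-squares fitting. Grows as
    (2n-5)!!, so only usable for tiny n.
    """
    def build(graphs, remaining):
        if not remaining:
            return graphs
        leaf = remaining[0]
        grown = []
        for g, next_i in graphs:
            for u, v in list(g.edges()):
                h = g.copy()
                mid = f"X{next_i}"
                h.remove_edge(u, v)
                h.add_edge(u, mid)
                h.add_edge(mid, v)
                h.add_edge(mid, leaf)
                grown.append((h, next_i + 1))
        return build(grown, remaining[1:])

    base = nx.Graph()
    for leaf in labels[:3]:
        base.add_edge("X0", leaf)
    for g, _ in build([(base, 1)], list(labels[3:])):
        anchor = min(labels)
        splits = set()
        for u, v in g.edges():
            h = g.copy()
            h.remove_edge(u, v)
            side = {
                x for x in nx.node_connected_component(h, u) if x in labels
            }
            if 2 <= len(side) <= len(labels) - 2:
                if anchor in side:
                    side = frozenset(set(labels) - side)
                splits.add(frozenset(side))
        yield splits, g


def best_topology_by_least_squares(matrix: DistanceMatrix):
    """Exhaustive search: the topology whose least-squares fit of edge
    lengths best reproduces the matrix (residual 0 for additive input)."""
    labels = matrix.labels
    best = None
    for splits, g in enumerate_topologies(labels):
        edges = list(g.edges())
        edge_index = {frozenset(e): k for k, e in enumerate(edges)}
        pairs = list(itertools.combinations(labels, 2))
        A = np.zeros((len(pairs), len(edges)))
        b = np.zeros(len(pairs))
        for row, (x, y) in enumerate(pairs):
            path = nx.shortest_path(g, x, y)
            for u, v in zip(path, path[1:]):
                A[row, edge_index[frozenset((u, v))]] = 1.0
            b[row] = matrix.get(x, y)
        fit, *_ = np.linalg.lstsq(A, b, rcond=None)
        residual = float(np.sum((A @ fit - b) ** 2))
        if best is None or residual < best[0]:
            best = (residual, splits)
    return best[1], best[0]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
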