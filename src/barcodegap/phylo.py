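"""Neighbor-joining trees with column-resampling bootstrap support.

NJ is the classic agglomerative distance method: at each step join the pair
(i, j) minimising

    S(i, j) = (m - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with branch lengths from the standard split formulas. It exactly recovers any
additive (tree-realisable) matrix. Determinism contracts: ties in S are broken
by the lexicographically smallest label pair (an internal node is keyed by the
smallest leaf beneath it), and negative branch lengths are clamped to zero
with the deficit moved to the sibling edge so path lengths are preserved.

Bootstrap support follows Felsenstein's procedure: alignment columns are
resampled with replacement, the K2P matrix and NJ tree are recomputed, and an
internal edge's support is the fraction of replicate trees containing its
bipartition. The reported tree is the NJ tree of the original data annotated
with these supports.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}  # transition partner = code ^ 1


@dataclass
class Node:
    """Tree node; ``length`` is the edge to the parent (root length unused)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


class Tree:
    """Unrooted binary phylogeny, stored rooted at a trifurcating node."""

    def __init__(self, root: Node):
        self.root = root

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial bipartitions, keyed by the canonical leaf-set side.

        The canonical side is the one *not* containing the alphabetically
        smallest leaf, so the same split always hashes identically.
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: dict[frozenset, Node] = {}

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out[side] = node
            return below

        walk(self.root)
        return out

    def annotate_supports(self, supports: dict[frozenset, float]) -> None:
        for side, node in self.bipartitions().items():
            node.support = supports.get(side, 0.0)

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (additivity checks)."""
        names = sorted(self.leaf_names)
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sides = []
            for child in node.children:
                depths = walk(child)
                sides.append({k: v + child.length for k, v in depths.items()})
            for sa, sb in itertools.combinations(sides, 2):
                for la, da in sa.items():
                    for lb, db in sb.items():
                        dist[index[la], index[lb]] = dist[index[lb], index[la]] = da + db
            merged = {}
            for s in sides:
                merged.update(s)
            return merged

        walk(self.root)
        return names, dist


def _tie_key(node: Node) -> str:
    return min(leaf.name for leaf in node.leaves())


def nj(matrix: DistanceMatrix) -> Tree:
    """Neighbor-joining tree of a distance matrix (no saturated entries)."""
    m = len(matrix)
    if m < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")
    if matrix.any_saturated:
        raise ValueError("matrix contains saturated pairs; resolve before NJ")

    D = matrix.values.copy()
    nodes = [Node(name=lab) for lab in matrix.labels]
    keys = [lab for lab in matrix.labels]

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i, j in itertools.combinations(range(n), 2):
            s = (n - 2) * D[i, j] - r[i] - r[j]
            pair_key = tuple(sorted((keys[i], keys[j])))
            cand = (s, pair_key, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        li, lj = li + 0.0, lj + 0.0  # normalise -0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = Node(children=[child_i, child_j])

        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        D = newD

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0) + 0.0
    return Tree(Node(children=list(nodes)))


@dataclass
class BootstrapResult:
    """Original-data NJ tree annotated with bootstrap supports."""

    tree: Tree
    supports: dict[frozenset, float]
    n_replicates: int
    n_dropped: int


def _encode(haplotypes) -> tuple[list[str], np.ndarray]:
    named = [
        h if isinstance(h, tuple) else (h.name, h.sequence) for h in haplotypes
    ]
    labels = [n for n, _ in named]
    L = len(named[0][1])
    codes = np.full((len(named), L), -1, dtype=np.int8)
    for row, (_, seq) in enumerate(named):
        if len(seq) != L:
            raise ValueError("haplotype sequences must share one length")
        codes[row] = [_CODE.get(ch, -1) for ch in seq]
    return labels, codes


def _pair_categories(codes: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Per-site category for every pair: 0 same, 1 transition, 2 transversion, 3 deleted."""
    n, L = codes.shape
    pairs = list(itertools.combinations(range(n), 2))
    cats = np.empty((len(pairs), L), dtype=np.int8)
    for row, (i, j) in enumerate(pairs):
        a, b = codes[i], codes[j]
        invalid = (a < 0) | (b < 0)
        same = a == b
        ts = (a >> 1 == b >> 1) & ~same  # same purine/pyrimidine class
        cat = np.full(L, 2, dtype=np.int8)
        cat[same] = 0
        cat[ts] = 1
        cat[invalid] = 3
        cats[row] = cat
    return pairs, cats


def _matrix_from_counts(labels, pairs, n_valid, n_ts, n_tv) -> DistanceMatrix | None:
    """Assemble a DistanceMatrix from per-pair counts; None if any pair saturated."""
    n = len(labels)
    values = np.zeros((n, n))
    for (i, j), nv, ts, tv in zip(pairs, n_valid, n_ts, n_tv):
        if nv == 0:
            return None
        P, Q = ts / nv, tv / nv
        arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if arg1 <= 0.0 or arg2 <= 0.0:
            return None
        values[i, j] = values[j, i] = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
    return DistanceMatrix(labels, values, np.zeros((n, n), dtype=bool))


def bootstrap(aligned_haplotypes, B: int, seed: int) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree.

    Each of the ``B`` replicates resamples alignment columns with replacement
    (seeded generator), recomputes the K2P matrix and NJ tree, and records its
    bipartitions. Replicates producing a saturated pair are dropped and
    logged; more than 10% dropped is an error. Support is the fraction of
    retained replicates containing each bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels, codes = _encode(aligned_haplotypes)
    L = codes.shape[1]
    pairs, cats = _pair_categories(codes)

    n_valid = (cats != 3).sum(axis=1)
    n_ts = (cats == 1).sum(axis=1)
    n_tv = (cats == 2).sum(axis=1)
    original = _matrix_from_counts(labels, pairs, n_valid, n_ts, n_tv)
    if original is None:
        raise ValueError("original data contain a saturated or empty pair")
    tree = nj(original)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, L, size=L)
        S = cats[:, idx]
        nv = (S != 3).sum(axis=1)
        ts = (S == 1).sum(axis=1)
        tv = (S == 2).sum(axis=1)
        rep = _matrix_from_counts(labels, pairs, nv, ts, tv)
        if rep is None:
            dropped += 1
            logger.warning("bootstrap replicate dropped (saturated pair)")
            continue
        for side in nj(rep).bipartitions():
            counts[side] = counts.get(side, 0) + 1
    if dropped > 0.1 * B:
        raise ValueError(
            f"{dropped}/{B} bootstrap replicates dropped due to saturation"
        )
    retained = B - dropped
    supports = {side: c / retained for side, c in counts.items()}
    tree.annotate_supports(supports)
    return BootstrapResult(
        tree=tree, supports=supports, n_replicates=retained, n_dropped=dropped
    )


def write_newick(tree: Tree, decimals: int = 6) -> str:
    """Serialise with branch lengths and integer percent supports as internal labels."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.{decimals}f}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else str(round(node.support * 100))
        return f"({inner}){label}:{node.length:.{decimals}f}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"
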