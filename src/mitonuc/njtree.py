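"""Neighbor-joining phylogeny from a distance matrix, and cherry extraction.

Standard Saitou–Nei agglomeration: at each step the pair minimizing

    Q(i, j) = (m - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined (m = number of active nodes), pendant lengths come from the usual
two-point formulas, and distances to the new node are
``(d(i,k) + d(j,k) - d(i,j)) / 2``.  On additive (four-point-condition)
inputs this recovers the generating topology and branch lengths exactly.

Numerical policies, both recorded in tree metadata:
- negative computed pendant lengths are clamped to zero with the deficit
  transferred to the sibling branch (so the cherry's total is preserved);
- argmin-Q ties break on the lowest (row, column) index pair in the current
  active ordering, making the output byte-deterministic.

A *cherry* (sister pair) is a pair of leaves attached to the same internal
node; internal nodes with more than two leaf neighbours (the 3-leaf star)
define no cherry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import count

import dendropy
import networkx as nx
import numpy as np

from .gendist import DistanceMatrix

__all__ = ["PhyloTree", "neighbor_joining", "sister_pairs"]

#: NJ is O(n^3); warn above this many leaves.
LARGE_TREE_WARN = 3000


@dataclass
class PhyloTree:
    """Unrooted tree as a networkx graph with 'length' edge attributes.

    ``leaf_labels`` maps node id → sample label for leaves.  ``root`` is a
    serialization anchor only (the tree itself is unrooted); degree-2 nodes
    are retained if the source had them, which matters for cherry
    semantics on literally-parsed rooted Newick strings.
    """

    graph: nx.Graph
    leaf_labels: dict[int, str]
    root: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            ln = data.get("length")
            if ln is None or not np.isfinite(ln) or ln < 0:
                raise ValueError(f"edge ({u},{v}) has invalid length {ln!r}")
        for n in self.graph.nodes:
            if self.graph.degree(n) <= 1 and n not in self.leaf_labels:
                raise ValueError(f"leaf node {n} has no label")

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    def leaf_set(self) -> set[str]:
        return set(self.leaf_labels.values())

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths between two leaves, by label."""
        inv = {lab: n for n, lab in self.leaf_labels.items()}
        return nx.shortest_path_length(
            self.graph, inv[a], inv[b], weight="length"
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse Newick, retaining the root node even if degree 2."""
        t = dendropy.Tree.get(data=newick, schema="newick")
        ids = count()
        node_id: dict = {}
        g = nx.Graph()
        labels: dict[int, str] = {}
        for nd in t.preorder_node_iter():
            i = next(ids)
            node_id[nd] = i
            g.add_node(i)
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon else ""
            if nd.parent_node is not None:
                ln = nd.edge.length if nd.edge.length is not None else 0.0
                g.add_edge(node_id[nd.parent_node], i, length=float(ln))
        return cls(graph=g, leaf_labels=labels, root=node_id[t.seed_node])


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Build an unrooted NJ tree from a labelled distance matrix."""
    n = D.n
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    if n > LARGE_TREE_WARN:
        warnings.warn(
            f"neighbor joining on {n} leaves is O(n^3); this will be slow",
            stacklevel=2,
        )
    g = nx.Graph()
    labels = {i: lab for i, lab in enumerate(D.labels)}
    g.add_nodes_from(range(n))
    next_id = count(n)

    active = list(range(n))
    d = D.values.astype(float).copy()
    # index into d for each active node
    pos = {node: i for i, node in enumerate(active)}

    def add_edge(u: int, v: int, length: float) -> None:
        g.add_edge(u, v, length=max(length, 0.0))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_([pos[a] for a in active], [pos[a] for a in active])]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, column) pair among ties: flat argmin is row-major
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        dij = sub[i, j]
        vi = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        u = next(next_id)
        add_edge(u, a, vi)
        add_edge(u, b, vj)
        # distances from u to remaining nodes
        new_row = np.empty(m)
        for t_idx, t_node in enumerate(active):
            new_row[t_idx] = (sub[i, t_idx] + sub[j, t_idx] - dij) / 2.0
        # replace a's slot with u, drop b
        pa, pb = pos[a], pos[b]
        d[pa, :] = 0.0
        d[:, pa] = 0.0
        for t_idx, t_node in enumerate(active):
            if t_node in (a, b):
                continue
            d[pa, pos[t_node]] = new_row[t_idx]
            d[pos[t_node], pa] = new_row[t_idx]
        pos[u] = pa
        del pos[a], pos[b]
        active[i] = u
        active.pop(j)

    # final three-taxon star: closed-form pendant lengths
    a, b, c = active
    dab = d[pos[a], pos[b]]
    dac = d[pos[a], pos[c]]
    dbc = d[pos[b], pos[c]]
    va = (dab + dac - dbc) / 2.0
    vb = (dab + dbc - dac) / 2.0
    vc = (dac + dbc - dab) / 2.0
    lens = {a: va, b: vb, c: vc}
    order = [a, b, c]
    for x in order:  # clamp-and-transfer on the star
        if lens[x] < 0:
            deficit = -lens[x]
            lens[x] = 0.0
            others = [y for y in order if y != x]
            for y in others:
                lens[y] += deficit / len(others)
    u = next(next_id)
    for x in order:
        add_edge(u, x, lens[x])

    return PhyloTree(
        graph=g,
        leaf_labels=labels,
        root=u,
        meta={"negative_branch_policy": "clamp-and-transfer", "tie_break": "lowest-index"},
    )


def sister_pairs(tree: PhyloTree) -> list[tuple[str, str]]:
    """All cherries: leaf pairs attached to the same internal node.

    Each pair is reported once, members sorted, pairs in sorted order.
    Internal nodes with a number of leaf neighbours other than two (e.g.
    the single node of a 3-leaf star) contribute nothing.
    """
    g = tree.graph
    labels = tree.leaf_labels
    out: list[tuple[str, str]] = []
    for node in g.nodes:
        if node in labels and g.degree(node) <= 1:
            continue
        leaf_nbrs = [n for n in g.neighbors(node) if n in labels and g.degree(n) == 1]
        if len(leaf_nbrs) == 2:
            pair = tuple(sorted(labels[n] for n in leaf_nbrs))
            out.append(pair)  # type: ignore[arg-type]
    return sorted(out)
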