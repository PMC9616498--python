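"""Weighted graph container and the standard (metadata-ignorant) random walk.

The walk is the usual discrete-time random walk on a weighted graph: a
walker at node ``k`` steps to node ``j`` with probability proportional to
the edge weight ``w_kj``.  The transition matrix is stored
*column-stochastically* — column ``k`` holds the out-distribution of node
``k`` — which keeps the downstream flow-propagation algebra free of
transposes.

Node identifiers are opaque strings.  Internally every node maps to a dense
0-based index (its position in :attr:`Graph.node_ids`) and all matrices use
that index, so edge lists, metadata tables, and partitions join stably on
the identifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Graph",
    "GraphError",
    "TransitionMatrix",
    "StationaryDistribution",
    "transition_matrix",
    "stationary_distribution",
]


class GraphError(ValueError):
    """Raised for structurally invalid graphs or unmet walk preconditions."""


@dataclass(frozen=True, eq=False)
class Graph:
    """A connected, weighted, possibly directed graph ``G = (V, L)``.

    Undirected edges are stored once and interpreted symmetrically.
    Self-loops are allowed and contribute their weight once to the node
    strength.  Connectivity (strong connectivity for directed graphs) is
    checked eagerly at construction; walk operations on a disconnected
    graph are meaningless, so such graphs are rejected outright.

    Parameters
    ----------
    node_ids
        Ordered node identifiers; order defines the dense internal index.
    edges
        ``(source, target, weight)`` triples with strictly positive,
        finite weights.  Parallel entries for the same ordered pair are
        summed.
    directed
        If False (default) each stored edge is interpreted symmetrically.
    """

    node_ids: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    directed: bool = False

    def __post_init__(self) -> None:
        if len(self.node_ids) == 0:
            raise GraphError("graph has no nodes")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise GraphError("duplicate node identifiers")
        index = self.index
        for s, t, w in self.edges:
            if s not in index or t not in index:
                raise GraphError(f"edge ({s!r}, {t!r}) references unknown node")
            if not np.isfinite(w) or w <= 0:
                raise GraphError(f"edge ({s!r}, {t!r}) has non-positive weight {w!r}")
        n_comp, _ = connected_components(
            self.weight_matrix, directed=self.directed, connection="strong"
        )
        if n_comp != 1:
            kind = "strongly connected" if self.directed else "connected"
            raise GraphError(
                f"graph is not {kind} ({n_comp} components); "
                "walk operations require a single component"
            )

    @classmethod
    def from_edges(
        cls,
        edges,
        nodes=None,
        directed: bool = False,
    ) -> "Graph":
        """Build a graph from an iterable of ``(src, dst[, weight])``.

        Node order is first appearance in the edge list unless ``nodes``
        is given explicitly (which may also declare isolated nodes — these
        are rejected later by the connectivity check unless N == 1).
        """
        norm = []
        seen: dict[str, None] = {}
        for e in edges:
            if len(e) == 2:
                s, t = e
                w = 1.0
            else:
                s, t, w = e
            s, t = str(s), str(t)
            norm.append((s, t, float(w)))
            seen.setdefault(s)
            seen.setdefault(t)
        node_ids = tuple(str(n) for n in nodes) if nodes is not None else tuple(seen)
        return cls(node_ids=node_ids, edges=tuple(norm), directed=directed)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def index(self) -> dict[str, int]:
        """Node identifier -> dense 0-based index."""
        return {v: i for i, v in enumerate(self.node_ids)}

    @cached_property
    def weight_matrix(self) -> sp.csr_array:
        """Weight matrix ``W[k, j] = w_kj`` (row = source).

        For undirected graphs both orientations are materialized; the
        diagonal holds each self-loop weight once.
        """
        n = self.n_nodes
        idx = self.index
        rows, cols, vals = [], [], []
        for s, t, w in self.edges:
            i, j = idx[s], idx[t]
            rows.append(i)
            cols.append(j)
            vals.append(w)
            if not self.directed and i != j:
                rows.append(j)
                cols.append(i)
                vals.append(w)
        w_mat = sp.coo_array(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
        )
        return w_mat.tocsr()

    @cached_property
    def strengths(self) -> np.ndarray:
        """Node strengths ``s_k = sum_j w_kj`` (out-strength if directed)."""
        return np.asarray(self.weight_matrix.sum(axis=1)).ravel()


@dataclass(frozen=True, eq=False)
class TransitionMatrix:
    """Column-stochastic one-step transition matrix.

    ``matrix[j, k]`` is the probability that a walker at ``k`` steps to
    ``j``; every column sums to 1.
    """

    node_ids: tuple[str, ...]
    matrix: sp.csc_array

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass(frozen=True, eq=False)
class StationaryDistribution:
    """Stationary visit rates ``p_i`` of the standard random walk."""

    node_ids: tuple[str, ...]
    p: np.ndarray


def transition_matrix(graph: Graph) -> TransitionMatrix:
    """One-step transition probabilities ``pi_jk = w_kj / sum_j w_kj``.

    Column ``k`` of the returned (column-stochastic) matrix is the
    out-distribution of node ``k``.
    """
    s = graph.strengths
    zero = np.flatnonzero(s <= 0)
    if zero.size:
        name = graph.node_ids[zero[0]]
        raise GraphError(f"node {name!r} has zero strength (isolated); no walk is defined")
    row_norm = graph.weight_matrix.multiply(1.0 / s[:, None])
    return TransitionMatrix(graph.node_ids, sp.csc_array(row_norm.T))


def stationary_distribution(
    graph: Graph, tol: float = 1e-12, max_iter: int = 100_000
) -> StationaryDistribution:
    """Stationary visit rates of the standard random walk on ``graph``.

    Undirected graphs use the closed form ``p_i = s_i / sum_k s_k``.
    Directed graphs use power iteration on the column-stochastic
    transition matrix until the L1 residual drops below ``tol``; failure
    to converge within ``max_iter`` indicates a non-primitive (e.g.
    periodic) chain and raises :class:`GraphError`.
    """
    if not graph.directed:
        s = graph.strengths
        return StationaryDistribution(graph.node_ids, s / s.sum())

    pi = transition_matrix(graph).matrix
    n = graph.n_nodes
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = pi @ x
        x_new /= x_new.sum()
        if np.abs(x_new - x).sum() < tol:
            return StationaryDistribution(graph.node_ids, x_new)
        x = x_new
    raise GraphError(
        "power iteration did not converge: the directed graph is likely "
        "not primitive (aperiodicity required)"
    )
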