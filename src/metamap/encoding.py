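"""Construction of the metadata-dependent encoding graph E.

A fragmented random walk restarts at a node ``i`` drawn proportionally to
the stationary visit rates ``p_i`` of the standard walk, steps through the
graph, and at each arrival node ``j`` encodes the transition ``i -> j``
with probability ``eps_ij``, terminating on success.  Aggregating encoded
transitions over many walks and normalizing by their number yields the
encoding graph ``E = {e_ij}``: a flow graph over ordered node pairs with
total flow 1.  ``E`` blends network structure with metadata and is
generally dense — ``e_ij`` can be positive for pairs not adjacent in the
input graph.

Two constructions are provided:

* :func:`closed_form_encoding_graph` — sums the transient series
  ``e_ij = sum_{t>=1} eps_ij * p_j(t|i)`` exactly, where the survivor
  mass obeys ``v(t+1) = Pi_tilde_i v(t)`` with
  ``pi_tilde_jk|i = pi_jk (1 - eps_ik)`` (jump k -> j after *not*
  encoding at k).  The default method sums the geometric series in
  closed form by solving ``(I - Pi_tilde_i) u = v(1)`` per source; a
  truncated power-series iteration is available as ``method="series"``.
* :func:`monte_carlo_encoding_graph` — simulates the fragmented walks
  directly; serves as an independent stochastic oracle for the closed
  form.

No encoding trial occurs at the walk's origin at t = 0: the first trial
happens after the first step, matching the verbal walk process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import Graph, StationaryDistribution, stationary_distribution, transition_matrix

__all__ = [
    "FlowGraph",
    "EncodingError",
    "closed_form_encoding_graph",
    "monte_carlo_encoding_graph",
    "flow_threshold",
]


class EncodingError(ValueError):
    """Raised when an encoding-graph construction cannot complete."""


@dataclass(frozen=True, eq=False)
class FlowGraph:
    """Nonnegative pairwise flows ``e_ij`` with total 1 (sparse, absent = 0).

    Storage is sparse but semantics are dense: any ordered pair not
    stored carries zero flow.
    """

    node_ids: tuple[str, ...]
    flows: sp.csr_array

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if self.flows.shape != (n, n):
            raise EncodingError("flow matrix shape does not match node count")
        if self.flows.nnz and self.flows.data.min() < 0:
            raise EncodingError("negative flow")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def total(self) -> float:
        return float(self.flows.sum())

    def source_flows(self) -> np.ndarray:
        """Per-source totals ``sum_j e_ij`` (row sums)."""
        return np.asarray(self.flows.sum(axis=1)).ravel()

    def visit_rates(self) -> np.ndarray:
        """Per-node encoded visit rates ``p_j = sum_i e_ij`` (column sums)."""
        return np.asarray(self.flows.sum(axis=0)).ravel()

    def toarray(self) -> np.ndarray:
        return self.flows.toarray()

    @classmethod
    def from_dense(cls, node_ids, dense: np.ndarray) -> "FlowGraph":
        return cls(tuple(node_ids), sp.csr_array(np.asarray(dense, dtype=float)))

    def to_tsv(self, path) -> None:
        """Write flows as ``src\\tdst\\tflow`` with 17 significant digits.

        A leading ``# nodes:`` comment preserves the node order so the
        round trip is exact even for nodes without outgoing flow.
        """
        coo = self.flows.tocoo()
        with open(path, "w") as fh:
            fh.write("# nodes:\t" + "\t".join(self.node_ids) + "\n")
            fh.write("src\tdst\tflow\n")
            order = np.lexsort((coo.col, coo.row))
            for k in order:
                i, j, v = coo.row[k], coo.col[k], coo.data[k]
                fh.write(f"{self.node_ids[i]}\t{self.node_ids[j]}\t{v:.17g}\n")

    @classmethod
    def from_tsv(cls, path) -> "FlowGraph":
        node_ids: list[str] | None = None
        rows, cols, vals = [], [], []
        entries: list[tuple[str, str, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("# nodes:"):
                    node_ids = line.split("\t")[1:]
                    continue
                parts = line.split("\t")
                if parts[:3] == ["src", "dst", "flow"]:
                    continue
                if len(parts) != 3:
                    raise EncodingError(f"{path}: malformed line {lineno}: {line!r}")
                entries.append((parts[0], parts[1], float(parts[2])))
        if node_ids is None:  # fall back to first-appearance order
            seen: dict[str, None] = {}
            for s, t, _ in entries:
                seen.setdefault(s)
                seen.setdefault(t)
            node_ids = list(seen)
        index = {v: i for i, v in enumerate(node_ids)}
        for s, t, v in entries:
            rows.append(index[s])
            cols.append(index[t])
            vals.append(v)
        n = len(node_ids)
        mat = sp.coo_array((vals, (rows, cols)), shape=(n, n)).tocsr()
        return cls(tuple(node_ids), mat)


def _stationary_vector(graph: Graph, p) -> np.ndarray:
    if p is None:
        return stationary_distribution(graph).p
    if isinstance(p, StationaryDistribution):
        return np.asarray(p.p, dtype=float)
    return np.asarray(p, dtype=float)


def closed_form_encoding_graph(
    graph: Graph,
    eps: np.ndarray,
    p=None,
    tol: float = 1e-10,
    t_max: int = 100_000,
    method: str = "solve",
) -> FlowGraph:
    """Encoding graph from the exact transient analysis, one source at a time.

    For each source ``i`` the first-step mass is ``v(1)_j = p_i pi_ji``
    (no encoding trial at the origin itself); each subsequent step first
    accumulates ``e_ij += eps_ij v(t)_j``, then propagates survivors
    ``v(t+1) = Pi_tilde_i v(t)`` with survival factor ``1 - eps_ik`` at
    node ``k``.

    ``method="solve"`` (default) sums the full series exactly through the
    fundamental-matrix identity ``u = (I - Pi_tilde_i)^{-1} v(1)``,
    ``e_ij = eps_ij u_j``.  ``method="series"`` iterates the series
    until the surviving mass drops below ``tol * p_i`` or ``t_max`` steps,
    erroring if more than 1% of the source mass is still unencoded at
    ``t_max``.  Either way row ``i`` is rescaled to sum to ``p_i``
    exactly, so the total flow is 1 by construction.
    """
    n = graph.n_nodes
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (n, n):
        raise EncodingError("eps must be an N x N array")
    if np.any(eps <= 0):
        raise EncodingError("eps must be floored above 0 (see epsilon_matrix)")
    pvec = _stationary_vector(graph, p)
    pi_dense = transition_matrix(graph).matrix.toarray()  # pi[j, k] = P(k -> j)

    flows = np.zeros((n, n))
    identity = np.eye(n)
    for i in range(n):
        v1 = pvec[i] * pi_dense[:, i]
        survive = 1.0 - eps[i]
        if method == "solve":
            # u_j = total survivor-weighted visits at j; geometric series
            # summed exactly: u = v1 + Pi_tilde_i u.
            a_mat = identity - pi_dense * survive[None, :]
            u = np.linalg.solve(a_mat, v1)
            e_row = eps[i] * u
        elif method == "series":
            v = v1
            e_row = np.zeros(n)
            target = tol * pvec[i]
            for _ in range(t_max):
                e_row += eps[i] * v
                v = v * survive
                mass = v.sum()
                if mass < target:
                    break
                v = pi_dense @ v
            else:
                if mass > 0.01 * pvec[i]:
                    raise EncodingError(
                        f"source {graph.node_ids[i]!r}: {mass / pvec[i]:.2%} of walk "
                        f"mass unencoded after t_max={t_max} steps; increase t_max "
                        "(eps may be too small)"
                    )
        else:
            raise EncodingError(f"unknown method {method!r}")
        e_row *= pvec[i] / e_row.sum()
        flows[i] = e_row
    return FlowGraph(graph.node_ids, sp.csr_array(flows))


def monte_carlo_encoding_graph(
    graph: Graph,
    eps: np.ndarray,
    p=None,
    n_walks: int = 1_000_000,
    seed: int = 0,
    max_steps: int = 10_000,
) -> FlowGraph:
    """Encoding graph estimated by simulating the fragmented walks.

    Each walk draws its source ``i`` proportionally to the exact
    stationary rates, steps by the transition matrix, and performs an
    encoding trial with probability ``eps_ij`` at every arrival ``j``;
    on success the ordered pair ``(i, j)`` is recorded and the walk ends.
    Flows are recorded counts normalized by the number of recorded walks,
    so the total is exactly 1.  Walks exceeding ``max_steps`` are
    discarded with a warning; a discard fraction above 0.1% is an error.
    """
    if n_walks < 1:
        raise EncodingError("n_walks must be >= 1")
    n = graph.n_nodes
    eps = np.asarray(eps, dtype=float)
    pvec = _stationary_vector(graph, p)
    pvec = pvec / pvec.sum()
    rng = np.random.default_rng(seed)

    # cum[k] = CDF over next nodes from k
    step_probs = transition_matrix(graph).matrix.toarray().T
    cum = np.cumsum(step_probs, axis=1)
    cum[:, -1] = 1.0

    src = rng.choice(n, size=n_walks, p=pvec)
    cur = src.copy()
    counts = np.zeros((n, n))
    discarded = 0
    for _ in range(max_steps):
        if cur.size == 0:
            break
        u = rng.random(cur.size)
        nxt = (cum[cur] > u[:, None]).argmax(axis=1)
        encode = rng.random(cur.size) < eps[src, nxt]
        np.add.at(counts, (src[encode], nxt[encode]), 1.0)
        keep = ~encode
        src = src[keep]
        cur = nxt[keep]
    else:
        discarded = cur.size
    recorded = n_walks - discarded
    if discarded:
        frac = discarded / n_walks
        if frac > 1e-3:
            raise EncodingError(
                f"{frac:.2%} of walks exceeded max_steps={max_steps}; "
                "increase max_steps or the encoding probabilities"
            )
        warnings.warn(
            f"discarded {discarded} of {n_walks} walks ({frac:.4%}) at max_steps",
            stacklevel=2,
        )
    return FlowGraph(graph.node_ids, sp.csr_array(counts / recorded))


def flow_threshold(flow_graph: FlowGraph, cutoff: float) -> FlowGraph:
    """Drop flows below ``cutoff`` and renormalize the rest to total 1.

    ``cutoff = 0`` is the identity (returns an equal copy, bit for bit).
    """
    if cutoff < 0:
        raise EncodingError("cutoff must be >= 0")
    mat = flow_graph.flows.copy()
    if cutoff == 0:
        return FlowGraph(flow_graph.node_ids, mat)
    mat.data[mat.data < cutoff] = 0.0
    mat.eliminate_zeros()
    total = mat.sum()
    if total == 0:
        raise EncodingError(f"cutoff {cutoff} removed all flows")
    mat = mat * (1.0 / total)
    return FlowGraph(flow_graph.node_ids, sp.csr_array(mat))
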