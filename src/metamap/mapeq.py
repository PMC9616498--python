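"""Two-level map equation on raw probability flows, and a greedy optimizer.

The map equation scores a partition M of the nodes by the expected number
of bits per encoded transition under a two-level Huffman-style codebook
scheme: an index codebook announces module entries, and one codebook per
module describes within-module visits plus the module exit.  Operating on
a :class:`~metamap.encoding.FlowGraph` directly (no re-modeling of flows),
with node visit rates ``p_j = sum_i e_ij``, module enter flow
``q_m^enter = sum_{i not in m, j in m} e_ij`` and exit flow
``q_m^exit = sum_{i in m, j not in m} e_ij``:

    L(M) = q H({q_m^enter / q}) + sum_m p_m^tot H({q_m^exit, p_j in m} / p_m^tot)

with ``q = sum_m q_m^enter``, ``p_m^tot = q_m^exit + sum_{j in m} p_j``
and ``H`` the Shannon entropy in bits.  Terms with zero rate contribute 0.

The optimizer is a seeded Louvain-style search: repeated passes of greedy
single-node moves to adjacent modules (sharing nonzero flow), aggregation
of modules into super-nodes, recursion, and node-level fine-tuning after
unfolding; the best of ``n_trials`` randomized restarts is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import adjusted_mutual_info_score

from .encoding import FlowGraph

__all__ = [
    "Partition",
    "MapEqError",
    "codelength",
    "optimize",
    "compare_partitions",
    "PartitionComparison",
]

_GAIN_TOL = 1e-12


class MapEqError(ValueError):
    """Raised for invalid partitions or flow graphs."""


@dataclass(frozen=True, eq=False)
class Partition:
    """Assignment of every node to exactly one module.

    Module ids are dense and 0-based; ``codelength`` (bits per encoding)
    is optional until evaluated.
    """

    node_ids: tuple[str, ...]
    modules: np.ndarray
    codelength: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.modules, dtype=np.int64)
        object.__setattr__(self, "modules", m)
        if m.shape != (len(self.node_ids),):
            raise MapEqError("modules must assign exactly one module per node")
        if m.size and (m.min() < 0 or set(np.unique(m)) != set(range(m.max() + 1))):
            raise MapEqError("module ids must be contiguous and 0-based")

    @classmethod
    def from_labels(cls, node_ids, labels, codelength: float | None = None) -> "Partition":
        """Build a partition from arbitrary hashable labels (compressed to 0..M-1
        in order of first appearance)."""
        seen: dict[object, int] = {}
        modules = np.array([seen.setdefault(l, len(seen)) for l in labels], dtype=np.int64)
        return cls(tuple(node_ids), modules, codelength)

    @property
    def n_modules(self) -> int:
        return int(self.modules.max()) + 1 if self.modules.size else 0

    def module_of(self, node_id: str) -> int:
        return int(self.modules[self.node_ids.index(node_id)])

    def members(self, module: int) -> tuple[str, ...]:
        return tuple(v for v, m in zip(self.node_ids, self.modules) if m == module)

    def to_dict(self) -> dict[str, int]:
        return {v: int(m) for v, m in zip(self.node_ids, self.modules)}

    def aligned_to(self, node_ids) -> np.ndarray:
        """Module labels reordered to ``node_ids``; errors on node-set mismatch."""
        if set(node_ids) != set(self.node_ids):
            raise MapEqError("partition node set does not match")
        d = self.to_dict()
        return np.array([d[v] for v in node_ids], dtype=np.int64)


def _plogp(x: np.ndarray) -> np.ndarray:
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out


def _codelength_from_labels(flows: sp.csr_array, labels: np.ndarray) -> float:
    coo = flows.tocoo()
    n_mod = int(labels.max()) + 1
    row_sum = np.asarray(flows.sum(axis=1)).ravel()
    col_sum = np.asarray(flows.sum(axis=0)).ravel()
    same = labels[coo.row] == labels[coo.col]
    int_m = np.bincount(labels[coo.row[same]], weights=coo.data[same], minlength=n_mod)
    in_m = np.bincount(labels, weights=col_sum, minlength=n_mod)
    out_m = np.bincount(labels, weights=row_sum, minlength=n_mod)
    enter = np.maximum(in_m - int_m, 0.0)
    exit_ = np.maximum(out_m - int_m, 0.0)
    p_tot = in_m + exit_
    q = enter.sum()
    return float(
        _plogp(np.array([q])).sum()
        - _plogp(enter).sum()
        - _plogp(exit_).sum()
        + _plogp(p_tot).sum()
        - _plogp(col_sum).sum()
    )


def codelength(flow_graph: FlowGraph, partition: Partition) -> float:
    """Two-level map-equation codelength of ``partition`` in bits per encoding."""
    total = flow_graph.total()
    if abs(total - 1.0) > 1e-6:
        raise MapEqError(f"flows total {total!r}, expected 1 within 1e-6")
    labels = partition.aligned_to(flow_graph.node_ids)
    return _codelength_from_labels(flow_graph.flows, labels)


# ---------------------------------------------------------------------------
# Greedy optimizer


def _local_moves(csr: sp.csr_array, csc: sp.csc_array, labels: np.ndarray,
                 rng: np.random.Generator, max_passes: int = 200) -> np.ndarray:
    """Greedy single-node moves to adjacent modules until a full pass is quiet."""
    n = csr.shape[0]
    m = labels.copy()
    n_slots = n  # labels < n always
    row_sum = np.asarray(csr.sum(axis=1)).ravel()
    col_sum = np.asarray(csr.sum(axis=0)).ravel()
    diag = csr.diagonal()
    coo = csr.tocoo()
    same = m[coo.row] == m[coo.col]
    int_m = np.bincount(m[coo.row[same]], weights=coo.data[same], minlength=n_slots)
    in_m = np.bincount(m, weights=col_sum, minlength=n_slots)
    out_m = np.bincount(m, weights=row_sum, minlength=n_slots)
    q = float(np.maximum(in_m - int_m, 0.0).sum())

    r_indptr, r_indices, r_data = csr.indptr, csr.indices, csr.data
    c_indptr, c_indices, c_data = csc.indptr, csc.indices, csc.data

    def plogp1(x: float) -> float:
        return x * np.log2(x) if x > 0 else 0.0

    for _ in range(max_passes):
        moved = 0
        for nd in rng.permutation(n):
            a = m[nd]
            sl = slice(r_indptr[nd], r_indptr[nd + 1])
            o_idx, o_val = r_indices[sl], r_data[sl]
            sl = slice(c_indptr[nd], c_indptr[nd + 1])
            i_idx, i_val = c_indices[sl], c_data[sl]
            keep_o = o_idx != nd
            keep_i = i_idx != nd
            mods_o = m[o_idx[keep_o]]
            mods_i = m[i_idx[keep_i]]
            cands = np.unique(np.concatenate((mods_o, mods_i)))
            cands = cands[cands != a]
            if cands.size == 0:
                continue
            d_out = np.bincount(mods_o, weights=o_val[keep_o], minlength=n_slots)
            d_in = np.bincount(mods_i, weights=i_val[keep_i], minlength=n_slots)
            e_self = diag[nd]
            ci, co = col_sum[nd], row_sum[nd]

            in_a2 = in_m[a] - ci
            out_a2 = out_m[a] - co
            int_a2 = int_m[a] - d_out[a] - d_in[a] - e_self
            in_b2 = in_m[cands] + ci
            out_b2 = out_m[cands] + co
            int_b2 = int_m[cands] + d_out[cands] + d_in[cands] + e_self

            enter_a, exit_a = in_m[a] - int_m[a], out_m[a] - int_m[a]
            ptot_a = in_m[a] + exit_a
            enter_b, exit_b = in_m[cands] - int_m[cands], out_m[cands] - int_m[cands]
            ptot_b = in_m[cands] + exit_b
            enter_a2, exit_a2 = in_a2 - int_a2, out_a2 - int_a2
            ptot_a2 = in_a2 + exit_a2
            enter_b2, exit_b2 = in_b2 - int_b2, out_b2 - int_b2
            ptot_b2 = in_b2 + exit_b2

            q2 = q + (enter_a2 + enter_b2) - (enter_a + enter_b)
            delta = (
                _plogp(q2) - plogp1(q)
                - (plogp1(enter_a2) + _plogp(enter_b2) - plogp1(enter_a) - _plogp(enter_b))
                - (plogp1(exit_a2) + _plogp(exit_b2) - plogp1(exit_a) - _plogp(exit_b))
                + (plogp1(ptot_a2) + _plogp(ptot_b2) - plogp1(ptot_a) - _plogp(ptot_b))
            )
            k = int(np.argmin(delta))  # ties -> lowest module id (cands sorted)
            if delta[k] < -_GAIN_TOL:
                b = int(cands[k])
                in_m[a], out_m[a], int_m[a] = in_a2, out_a2, int_a2
                in_m[b], out_m[b], int_m[b] = in_b2[k], out_b2[k], int_b2[k]
                q = float(q2[k])
                m[nd] = b
                moved += 1
        if moved == 0:
            break
    return m


def _compress(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv.astype(np.int64)


def _aggregate(flows: sp.csr_array, labels: np.ndarray) -> sp.csr_array:
    coo = flows.tocoo()
    n_mod = int(labels.max()) + 1
    agg = sp.coo_array(
        (coo.data, (labels[coo.row], labels[coo.col])), shape=(n_mod, n_mod)
    )
    return agg.tocsr()


def _optimize_single(flows: sp.csr_array, rng: np.random.Generator) -> np.ndarray:
    n = flows.shape[0]
    labels = _compress(_local_moves(flows, sp.csc_array(flows), np.arange(n), rng))
    n_mod = int(labels.max()) + 1
    if 1 < n_mod < n:
        agg = _aggregate(flows, labels)
        labels = _compress(_optimize_single(agg, rng)[labels])
        # fine-tune with node-level moves after unfolding
        labels = _compress(_local_moves(flows, sp.csc_array(flows), labels, rng))
    return labels


def _merge_to_cap(flows: sp.csr_array, labels: np.ndarray, cap: int) -> np.ndarray:
    labels = _compress(labels)
    while int(labels.max()) + 1 > cap:
        agg = _aggregate(flows, labels)
        n_mod = agg.shape[0]
        base = np.arange(n_mod)
        best = None
        for a in range(n_mod):
            for b in range(a + 1, n_mod):
                merged = base.copy()
                merged[b] = a
                length = _codelength_from_labels(agg, _compress(merged))
                if best is None or length < best[0] - _GAIN_TOL:
                    best = (length, a, b)
        _, a, b = best
        lab = labels.copy()
        lab[labels == b] = a
        labels = _compress(lab)
    return labels


def optimize(
    flow_graph: FlowGraph,
    n_trials: int = 10,
    seed: int = 0,
    max_modules: int | None = None,
) -> Partition:
    """Minimize the two-level codelength over partitions of ``flow_graph``.

    Runs ``n_trials`` seeded greedy searches from singleton modules and
    returns the best.  With ``max_modules``, modules of the best solution
    are pairwise-merged (least codelength increase first) until the cap
    is met.  Deterministic given ``(seed, n_trials)``.
    """
    total = flow_graph.total()
    if abs(total - 1.0) > 1e-6:
        raise MapEqError(f"flows total {total!r}, expected 1 within 1e-6")
    flows = sp.csr_array(flow_graph.flows)
    best_labels, best_len = None, np.inf
    for child in np.random.SeedSequence(seed).spawn(n_trials):
        rng = np.random.default_rng(child)
        labels = _optimize_single(flows, rng)
        length = _codelength_from_labels(flows, labels)
        if length < best_len - _GAIN_TOL:
            best_labels, best_len = labels, length
    if max_modules is not None and int(best_labels.max()) + 1 > max_modules:
        best_labels = _merge_to_cap(flows, best_labels, max_modules)
        best_len = _codelength_from_labels(flows, best_labels)
    return Partition.from_labels(flow_graph.node_ids, best_labels, codelength=best_len)


# ---------------------------------------------------------------------------
# Partition comparison


@dataclass(frozen=True, eq=False)
class PartitionComparison:
    """Similarity in [0, 1] (adjusted mutual information, clipped at 0)
    plus the module-to-module contingency table (rows = a, columns = b)."""

    similarity: float
    contingency: pd.DataFrame


def compare_partitions(a: Partition, b: Partition) -> PartitionComparison:
    """Chance-corrected similarity between two partitions of the same nodes.

    Equals 1 iff the partitions are identical up to module relabeling and
    is 0 in expectation for independent random partitions.
    """
    if set(a.node_ids) != set(b.node_ids):
        diff = set(a.node_ids) ^ set(b.node_ids)
        raise MapEqError(f"partitions cover different node sets (difference: {sorted(diff)})")
    la = a.modules
    lb = b.aligned_to(a.node_ids)
    ami = adjusted_mutual_info_score(la, lb)
    table = pd.crosstab(pd.Series(la, name="a"), pd.Series(lb, name="b"))
    return PartitionComparison(similarity=float(np.clip(ami, 0.0, 1.0)), contingency=table)
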