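"""Diagnostics relating partitions to categorical metadata.

Mixing ratio — per-category fraction of same-category node pairs that are
co-assigned to one community, averaged over categories:

    r_m = (1 / N_cat) * sum_k a_k / (n_k (n_k - 1) / 2)

where ``a_k`` counts same-community pairs of category ``k`` and ``n_k``
is the category size.  ``r_m = 1`` iff every category is contained in a
single community; the all-singleton partition gives 0 (when every
``n_k >= 2``).

Class overlap — for categories alpha, beta over communities C:

    m_ab = 1/(N_a + N_b) * sum_{c in C} (N_ca + N_cb) * (1 - delta(N_ca,0) delta(N_cb,0))

with ``N_ca`` the count of category alpha in community ``c``; ``m_ab = 0``
iff no community mixes the two categories, and ``m_aa = 1`` always.  The
row-normalized counterpart is ``m~_ab = m_ab / sum_b m_ab``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import closed_form_encoding_graph
from .graph import Graph, stationary_distribution
from .mapeq import Partition, optimize
from .metadata import (
    CategoricalParams,
    ContinuousParams,
    MetadataError,
    MetadataMap,
    epsilon_matrix,
)

__all__ = [
    "MixingRatio",
    "OverlapMatrix",
    "MetricsError",
    "mixing_ratio",
    "class_overlap",
    "quantile_bin",
    "sweep",
]


class MetricsError(ValueError):
    """Raised for metric preconditions that cannot be met."""


@dataclass(frozen=True, eq=False)
class MixingRatio:
    """Mixing ratio ``r_m`` with its per-category terms."""

    value: float
    per_category: dict[int, float]


@dataclass(frozen=True, eq=False)
class OverlapMatrix:
    """Class-overlap matrix ``m`` and its row-normalized form ``m~``."""

    categories: tuple[int, ...]
    m: np.ndarray
    m_tilde: np.ndarray

    def as_frame(self, normalized: bool = False) -> pd.DataFrame:
        mat = self.m_tilde if normalized else self.m
        return pd.DataFrame(mat, index=self.categories, columns=self.categories)


def _categorical_arrays(partition: Partition, meta: MetadataMap):
    if meta.kind != "categorical":
        raise MetricsError(
            "categorical metadata required; bin continuous metadata first "
            "(see quantile_bin)"
        )
    missing = [v for v in partition.node_ids if v not in meta.values]
    if missing:
        raise MetadataError(f"nodes without metadata: {missing}")
    cats = np.array([int(meta.values[v]) for v in partition.node_ids])
    return cats, partition.modules


def mixing_ratio(partition: Partition, meta: MetadataMap) -> MixingRatio:
    """Mixing ratio ``r_m`` of a partition against categorical metadata.

    Categories with a single node have a vacuously satisfied constraint;
    their term is 1 and a warning is issued.
    """
    cats, mods = _categorical_arrays(partition, meta)
    terms: dict[int, float] = {}
    for k in np.unique(cats):
        members = mods[cats == k]
        n_k = members.size
        if n_k == 1:
            warnings.warn(
                f"category {k} has a single node; its mixing term is vacuously 1",
                stacklevel=2,
            )
            terms[int(k)] = 1.0
            continue
        counts = np.bincount(members)
        a_k = (counts * (counts - 1) // 2).sum()
        terms[int(k)] = float(a_k / (n_k * (n_k - 1) / 2))
    return MixingRatio(value=float(np.mean(list(terms.values()))), per_category=terms)


def class_overlap(partition: Partition, meta: MetadataMap) -> OverlapMatrix:
    """Class-overlap matrix ``m_ab`` and row-normalized ``m~_ab``."""
    cats, mods = _categorical_arrays(partition, meta)
    cat_ids = np.unique(cats)
    # counts[c, a] = number of nodes of category a in community c
    counts = (
        pd.crosstab(pd.Series(mods), pd.Series(cats))
        .reindex(columns=cat_ids, fill_value=0)
        .to_numpy()
    )
    n_cat = cat_ids.size
    totals = counts.sum(axis=0)
    m = np.zeros((n_cat, n_cat))
    for a in range(n_cat):
        for b in range(n_cat):
            mixed = (counts[:, a] > 0) & (counts[:, b] > 0)
            m[a, b] = ((counts[:, a] + counts[:, b]) * mixed).sum() / (
                totals[a] + totals[b]
            )
    row = m.sum(axis=1, keepdims=True)
    if np.any(row == 0):
        raise MetricsError("a category overlaps nothing, cannot row-normalize")
    return OverlapMatrix(tuple(int(c) for c in cat_ids), m, m / row)


def quantile_bin(meta: MetadataMap, n_bins: int = 4) -> MetadataMap:
    """Discretize continuous metadata into quantile classes (quartiles by default)."""
    if meta.kind != "continuous":
        raise MetricsError("quantile_bin requires continuous metadata")
    nodes = list(meta.values)
    x = pd.Series([float(meta.values[v]) for v in nodes])
    binned = pd.qcut(x, n_bins, labels=False, duplicates="drop")
    return MetadataMap(
        values={v: int(b) for v, b in zip(nodes, binned)}, kind="categorical"
    )


def sweep(
    graph: Graph,
    meta: MetadataMap,
    params_grid,
    n_trials: int = 10,
    seed: int = 0,
    tol: float = 1e-10,
    t_max: int = 100_000,
    max_modules: int | None = None,
) -> pd.DataFrame:
    """Encoding-graph construction + optimization + metrics over a parameter grid.

    One row per parameter point with the point's parameters, the optimized
    codelength, the module count, and the mixing ratio ``r_m`` (continuous
    metadata is quartile-binned for ``r_m``).  All stages are seeded from
    ``seed``; rerunning is deterministic.
    """
    params_grid = list(params_grid)
    if not params_grid:
        raise MetricsError("empty parameter grid")
    p_stat = stationary_distribution(graph)
    meta_cat = meta if meta.kind == "categorical" else quantile_bin(meta)
    rows = []
    for params, child in zip(params_grid, np.random.SeedSequence(seed).spawn(len(params_grid))):
        eps = epsilon_matrix(graph, meta, params)
        flow_graph = closed_form_encoding_graph(graph, eps, p_stat, tol=tol, t_max=t_max)
        trial_seed = int(child.generate_state(1)[0] % 2**31)
        part = optimize(flow_graph, n_trials=n_trials, seed=trial_seed, max_modules=max_modules)
        row: dict[str, object] = {}
        if isinstance(params, CategoricalParams):
            row.update(p=params.p, c=params.c)
        elif isinstance(params, ContinuousParams):
            row.update(p=params.p, b=params.b, s=params.s)
        row.update(
            codelength=part.codelength,
            n_modules=part.n_modules,
            r_m=mixing_ratio(part, meta_cat).value,
        )
        rows.append(row)
    return pd.DataFrame(rows)
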