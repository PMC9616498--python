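"""Node metadata and metadata-dependent encoding probabilities.

Every node ``i`` carries a metadata value ``f_i`` — an integer category or
a real scalar.  The encoding probability ``eps_ij`` is the probability
that a walker that restarted at node ``i`` records ("encodes") its
transition upon arriving at node ``j``; it depends only on ``f_i`` and
``f_j``.

Categorical model (baseline probability ``p``, class contrast ``c``)::

    eps_ij = p            if f_i == f_j
           = p / c        otherwise

with three regimes: assortative (``c > 1``, same-class encoding is more
likely), neutral (``c = 1``, metadata irrelevant), and disassortative
(``p < c < 1``).

Continuous model (same-value probability ``p``, scale ``b``, metadata
strength ``s``), in its literal form::

    eps_ij = s * exp(-|f_i - f_j| / b) * p + (1 - s)

At ``s = 1`` and binary metadata one unit apart this reduces exactly to
the categorical model with ``c = exp(1/b)``.  For ``s < 1`` the literal
form gives ``eps = s*p + (1 - s)`` at ``|Δf| = 0``, i.e. not ``p``; a
self-consistent *factored* variant ``eps = p * (s*exp(-|Δf|/b) + 1 - s)``
is selectable via ``ContinuousParams(form="factored")``.  The literal form
is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .graph import Graph

__all__ = [
    "MetadataMap",
    "MetadataError",
    "CategoricalParams",
    "ContinuousParams",
    "categorical_epsilon",
    "continuous_epsilon",
    "standardize_metadata",
    "epsilon_matrix",
    "EPSILON_FLOOR",
]

#: Lower clamp applied to encoding probabilities before walk dynamics.
#: An exactly-zero eps along a whole trajectory would make walks
#: never terminate; the floor guarantees almost-sure encoding while
#: perturbing flows negligibly.
EPSILON_FLOOR = 1e-12


class MetadataError(ValueError):
    """Raised for invalid metadata maps or encoding parameters."""


@dataclass(frozen=True, eq=False)
class MetadataMap:
    """The map ``f : V -> S`` assigning each node a metadata value.

    ``kind`` is ``"categorical"`` (integer labels) or ``"continuous"``
    (finite real scalars).  ``labels``, if present, records the original
    string label for each internal integer category.
    """

    values: Mapping[str, object]
    kind: str
    labels: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise MetadataError(f"unknown metadata kind {self.kind!r}")
        for node, v in self.values.items():
            if self.kind == "continuous" and not math.isfinite(float(v)):
                raise MetadataError(f"non-finite metadata value for node {node!r}")

    def array_for(self, graph: Graph) -> np.ndarray:
        """Metadata values in the graph's node order; errors list missing ids."""
        missing = [v for v in graph.node_ids if v not in self.values]
        if missing:
            raise MetadataError(f"nodes without metadata: {missing}")
        dtype = np.int64 if self.kind == "categorical" else float
        return np.array([self.values[v] for v in graph.node_ids], dtype=dtype)

    @property
    def categories(self) -> list[int]:
        if self.kind != "categorical":
            raise MetadataError("continuous metadata has no categories")
        return sorted({int(v) for v in self.values.values()})


@dataclass(frozen=True)
class CategoricalParams:
    """Parameters of the categorical encoding model.

    ``p`` in (0, 1] is the same-class encoding probability; ``c >= p``
    is the class contrast, so the cross-class probability ``p / c`` lies
    in (0, 1].
    """

    p: float
    c: float

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise MetadataError(f"p must be in (0, 1], got {self.p}")
        if self.c < self.p:
            raise MetadataError(f"c must be >= p, got c={self.c} < p={self.p}")

    @property
    def cross(self) -> float:
        """Cross-class encoding probability ``p / c``."""
        return self.p / self.c


@dataclass(frozen=True)
class ContinuousParams:
    """Parameters of the continuous (real-valued metadata) encoding model.

    ``p`` in (0, 1] is the encoding probability at zero metadata distance
    (at ``s = 1``); ``b > 0`` is the scale on which metadata distance
    suppresses encoding; ``s`` in [0, 1] is the metadata strength, with
    baseline coding probability ``1 - s`` at large distance.  With
    ``standardize`` (default) metadata is z-scored before distances are
    taken, so ``b`` is measured in SDs.
    """

    p: float
    b: float
    s: float
    standardize: bool = True
    form: str = "literal"

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise MetadataError(f"p must be in (0, 1], got {self.p}")
        if self.b <= 0:
            raise MetadataError(f"b must be positive, got {self.b}")
        if not (0 <= self.s <= 1):
            raise MetadataError(f"s must be in [0, 1], got {self.s}")
        if self.form not in ("literal", "factored"):
            raise MetadataError(f"form must be 'literal' or 'factored', got {self.form!r}")


def categorical_epsilon(f_i, f_j, params: CategoricalParams):
    """Encoding probability for categorical metadata: ``p`` same class, ``p/c`` across."""
    same = np.asarray(f_i) == np.asarray(f_j)
    out = np.where(same, params.p, params.cross)
    return float(out) if out.ndim == 0 else out


def continuous_epsilon(f_i, f_j, params: ContinuousParams):
    """Encoding probability for real-valued metadata.

    Depends only on ``|f_i - f_j|`` and is non-increasing in it whenever
    ``s > 0``.  The result is clamped to [0, 1].
    """
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    if not (np.all(np.isfinite(f_i)) and np.all(np.isfinite(f_j))):
        raise MetadataError("non-finite metadata value")
    decay = np.exp(-np.abs(f_i - f_j) / params.b)
    if params.form == "literal":
        eps = params.s * decay * params.p + (1.0 - params.s)
    else:
        eps = params.p * (params.s * decay + (1.0 - params.s))
    eps = np.clip(eps, 0.0, 1.0)
    return float(eps) if eps.ndim == 0 else eps


def standardize_metadata(meta: MetadataMap) -> MetadataMap:
    """Z-score continuous metadata to mean 0, SD 1 (population convention)."""
    if meta.kind != "continuous":
        raise MetadataError("standardize_metadata requires continuous metadata")
    nodes = list(meta.values)
    x = np.array([float(meta.values[v]) for v in nodes])
    sd = x.std()  # population (ddof=0)
    if sd == 0:
        raise MetadataError("metadata is constant (zero variance); cannot standardize")
    z = (x - x.mean()) / sd
    return replace(meta, values=dict(zip(nodes, z.tolist())))


def epsilon_matrix(
    graph: Graph,
    meta: MetadataMap,
    params: CategoricalParams | ContinuousParams,
    floor: float = EPSILON_FLOOR,
) -> np.ndarray:
    """Dense N x N table of encoding probabilities ``eps_ij``.

    ``eps[i, j]`` applies to walkers restarted at ``i`` arriving at ``j``
    — including non-adjacent pairs, since walkers can take several steps.
    Entries are clamped to ``[floor, 1]`` before use in walk dynamics.
    """
    if isinstance(params, CategoricalParams):
        if meta.kind != "categorical":
            raise MetadataError("CategoricalParams requires categorical metadata")
        f = meta.array_for(graph)
        eps = np.where(f[:, None] == f[None, :], params.p, params.cross)
    elif isinstance(params, ContinuousParams):
        if meta.kind != "continuous":
            raise MetadataError("ContinuousParams requires continuous metadata")
        if params.standardize:
            meta = standardize_metadata(meta)
        f = meta.array_for(graph)
        eps = continuous_epsilon(f[:, None], f[None, :], params)
    else:
        raise MetadataError(f"unknown parameter type {type(params).__name__}")
    return np.clip(eps, floor, 1.0)
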