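"""Synthetic benchmarks with planted community structure and metadata.

Two generators:

* :func:`clique_benchmark` — three cliques K9, K15, K21 joined by one
  inter-clique edge per clique pair, with three balanced metadata classes
  inside each clique.  Depending on the encoding parameters, community
  detection on the encoding graph yields the three cliques (structure
  only), nine clique-by-class submodules, or three class-pure modules
  spanning cliques.
* :func:`ring_model` — ``N_c`` equal communities arranged on a ring;
  Bernoulli links with probability ``p1`` within a community and ``p2``
  between ring-adjacent communities, nothing else.  Metadata initially
  equals the planted community id; :func:`reshuffle_metadata` then swaps
  metadata between nodes whose planted communities sit at ring distance
  exactly ``d_c``, degrading the structure–metadata correlation in a
  controlled, distance-constrained way.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .graph import Graph, GraphError
from .mapeq import Partition
from .metadata import MetadataMap

__all__ = ["clique_benchmark", "ring_model", "reshuffle_metadata", "ring_distance"]


def clique_benchmark(
    seed: int = 0,
    clique_sizes: tuple[int, ...] = (9, 15, 21),
    n_classes: int = 3,
    links_per_pair: int = 3,
) -> tuple[Graph, MetadataMap]:
    """Three complete cliques with balanced classes and sparse inter-clique links.

    Classes are assigned round-robin inside each clique (sizes must be
    divisible by ``n_classes``, giving exactly one third per class for the
    defaults).  Each clique pair is joined by ``links_per_pair`` unit-weight
    edges whose endpoints are drawn (seeded) from a common random class, so
    the bridges respect the metadata.  The default of three bridges per
    clique pair keeps escape from a clique rare but possible: with a single
    bridge the metadata-dominated regime (small ``p``, large ``c``) cannot
    outweigh the clique-by-class split, while with three bridges all three
    regimes — structural, clique-by-class, and class-pure — are stable
    across seeds.
    """
    rng = np.random.default_rng(seed)
    if any(s % n_classes for s in clique_sizes):
        raise ValueError("clique sizes must be divisible by the number of classes")
    node_ids: list[str] = []
    classes: dict[str, int] = {}
    members: list[list[str]] = []
    for q, size in enumerate(clique_sizes):
        ids = [f"q{q}n{k}" for k in range(size)]
        node_ids.extend(ids)
        members.append(ids)
        for k, v in enumerate(ids):
            classes[v] = k % n_classes
    edges: list[tuple[str, str, float]] = []
    for ids in members:
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                edges.append((ids[a], ids[b], 1.0))
    for q1 in range(len(members)):
        for q2 in range(q1 + 1, len(members)):
            for _ in range(links_per_pair):
                cls = int(rng.integers(n_classes))
                u = rng.choice([v for v in members[q1] if classes[v] == cls])
                v = rng.choice([w for w in members[q2] if classes[w] == cls])
                edges.append((str(u), str(v), 1.0))
    graph = Graph(tuple(node_ids), tuple(edges), directed=False)
    return graph, MetadataMap(values=classes, kind="categorical")


def ring_distance(a: int, b: int, n_communities: int) -> int:
    """Shortest arc between community indices on the ring."""
    d = abs(a - b) % n_communities
    return min(d, n_communities - d)


def ring_model(
    n_nodes: int = 240,
    n_communities: int = 8,
    p1: float = 0.6,
    p2: float = 0.2,
    seed: int = 0,
    max_retries: int = 20,
) -> tuple[Graph, MetadataMap, Partition]:
    """Ring of ``n_communities`` planted communities with Bernoulli links.

    Links (unit weight) appear independently with probability ``p1``
    inside a community and ``p2`` between ring-adjacent communities; pairs
    of non-adjacent communities are never linked.  Metadata equals the
    planted community id.  A disconnected draw is regenerated from a fresh
    child seed, up to ``max_retries`` times.
    """
    if n_nodes % n_communities:
        raise ValueError("n_nodes must be divisible by n_communities")
    if not (0 < p2 <= p1 <= 1):
        raise ValueError("need 0 < p2 <= p1 <= 1")
    size = n_nodes // n_communities
    comm = np.repeat(np.arange(n_communities), size)
    node_ids = tuple(f"n{k}" for k in range(n_nodes))
    for child in np.random.SeedSequence(seed).spawn(max_retries):
        rng = np.random.default_rng(child)
        edges: list[tuple[str, str, float]] = []
        for a in range(n_nodes):
            for b in range(a + 1, n_nodes):
                d = ring_distance(int(comm[a]), int(comm[b]), n_communities)
                if d == 0:
                    prob = p1
                elif d == 1:
                    prob = p2
                else:
                    continue
                if rng.random() < prob:
                    edges.append((node_ids[a], node_ids[b], 1.0))
        try:
            graph = Graph(node_ids, tuple(edges), directed=False)
        except GraphError:
            continue
        meta = MetadataMap(
            values={v: int(c) for v, c in zip(node_ids, comm)}, kind="categorical"
        )
        planted = Partition(node_ids, comm.copy())
        return graph, meta, planted
    raise GraphError(
        f"no connected draw in {max_retries} attempts; increase p2 or the retry budget"
    )


def reshuffle_metadata(
    meta: MetadataMap,
    planted: Partition,
    d_c: int,
    n_steps: int,
    seed: int = 0,
) -> MetadataMap:
    """Swap metadata between node pairs at planted ring distance exactly ``d_c``.

    Each of the ``n_steps`` iterations draws a uniform random eligible
    node pair and swaps their metadata values, so the multiset of labels
    is preserved.  ``d_c`` must lie in [1, floor(N_c / 2)].
    """
    n_comm = planted.n_modules
    if not (1 <= d_c <= n_comm // 2):
        raise ValueError(f"d_c must be in [1, {n_comm // 2}], got {d_c}")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    by_comm: dict[int, list[str]] = {}
    for v, c in zip(planted.node_ids, planted.modules):
        by_comm.setdefault(int(c), []).append(v)
    pairs = [
        (a, b)
        for a in range(n_comm)
        for b in range(a + 1, n_comm)
        if ring_distance(a, b, n_comm) == d_c
    ]
    if not pairs:
        raise ValueError(f"no community pair at ring distance {d_c}")
    weights = np.array([len(by_comm[a]) * len(by_comm[b]) for a, b in pairs], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    values = dict(meta.values)
    for _ in range(n_steps):
        a, b = pairs[rng.choice(len(pairs), p=weights)]
        u = by_comm[a][rng.integers(len(by_comm[a]))]
        v = by_comm[b][rng.integers(len(by_comm[b]))]
        values[u], values[v] = values[v], values[u]
    return replace(meta, values=values)
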