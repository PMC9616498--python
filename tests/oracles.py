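"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the library's own computational paths:
set partitions are enumerated directly, codelengths are expanded term by
term from entropies, and random-walk statistics are simulated step by
step.
"""

from __future__ import annotations

import numpy as np


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    a = [0] * n
    b = [0] * n
    yield np.array(a)
    while True:
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[j - 1]
        yield np.array(a)


def entropy_bits(weights) -> float:
    """Shannon entropy (bits) of a nonnegative weight vector, normalized."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        return 0.0
    q = w / w.sum()
    return float(-(q * np.log2(q)).sum())


def two_level_codelength(flows: np.ndarray, labels: np.ndarray) -> float:
    """Term-by-term expansion of the two-level map equation on raw flows."""
    labels = np.asarray(labels)
    p_node = flows.sum(axis=0)
    modules = np.unique(labels)
    enters, length = [], 0.0
    for m in modules:
        inside = labels == m
        enters.append(flows[np.ix_(~inside, inside)].sum())
    q = float(np.sum(enters))
    length += q * entropy_bits(enters)
    for m, _enter in zip(modules, enters):
        inside = labels == m
        exit_m = flows[np.ix_(inside, ~inside)].sum()
        book = np.concatenate(([exit_m], p_node[inside]))
        length += book.sum() * entropy_bits(book)
    return length


def simulate_visit_frequencies(weight_matrix: np.ndarray, n_steps: int, seed: int):
    """Empirical visit frequencies of a long weighted random walk."""
    rng = np.random.default_rng(seed)
    n = weight_matrix.shape[0]
    counts = np.zeros(n)
    node = 0
    for _ in range(n_steps):
        w = weight_matrix[node]
        node = rng.choice(n, p=w / w.sum())
        counts[node] += 1
    return counts / counts.sum()


def absorbing_two_node_flows(eps0: float):
    """Closed-form encoding flows on the single-edge graph a-b, constant eps.

    A walk from a alternates arrivals b, a, b, ...; each arrival encodes
    with probability eps0, so the geometric series gives
    e_ab = p_a * eps0 / (1 - (1-eps0)^2) and
    e_aa = p_a * eps0 (1-eps0) / (1 - (1-eps0)^2); symmetrically for b.
    """
    p_a = 0.5
    denom = 1.0 - (1.0 - eps0) ** 2
    e_cross = p_a * eps0 / denom
    e_self = p_a * eps0 * (1.0 - eps0) / denom
    return np.array([[e_self, e_cross], [e_cross, e_self]])


def pair_counting_mixing_ratio(labels_mod, labels_cat) -> float:
    """Mixing ratio by explicit enumeration of all node pairs."""
    labels_mod = np.asarray(labels_mod)
    labels_cat = np.asarray(labels_cat)
    terms = []
    for k in np.unique(labels_cat):
        nodes = np.flatnonzero(labels_cat == k)
        if nodes.size == 1:
            terms.append(1.0)
            continue
        same = sum(
            1
            for x in range(nodes.size)
            for y in range(x + 1, nodes.size)
            if labels_mod[nodes[x]] == labels_mod[nodes[y]]
        )
        terms.append(same / (nodes.size * (nodes.size - 1) / 2))
    return float(np.mean(terms))
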