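"""Readers and writers for the supported file carriers.

Graphs: edge-list TSV (``src  dst  [weight]``, optional header, weight
defaults to 1) and Pajek ``.net`` (via networkx; ``*Arcs`` sections yield
directed graphs).  Metadata: TSV ``node_id  value`` with the kind inferred
(integers -> categorical, other numbers -> continuous, strings -> mapped
to integer categories) or forced.  Partitions: Pajek ``.clu`` (1-based
module ids in graph node order) and TSV.  All carriers round-trip:
``read(write(x)) == x``.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graph import Graph, GraphError
from .mapeq import MapEqError, Partition
from .metadata import MetadataError, MetadataMap

__all__ = [
    "read_graph",
    "write_graph",
    "read_edgelist",
    "write_edgelist",
    "read_pajek",
    "write_pajek",
    "read_metadata",
    "write_metadata",
    "read_partition",
    "write_partition",
]

_EDGELIST_HEADERS = {("src", "dst"), ("src", "dst", "weight"), ("source", "target"),
                     ("source", "target", "weight")}


def read_edgelist(path, directed: bool = False) -> Graph:
    """Read a TSV edge list; the optional header row is detected by name.

    A ``# nodes:`` comment (written by :func:`write_edgelist`) pins the
    node order; otherwise order of first appearance is used.
    """
    edges = []
    nodes = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("# nodes:"):
                nodes = line.split("\t")[1:]
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not edges and tuple(p.lower() for p in parts) in _EDGELIST_HEADERS:
                continue
            if len(parts) not in (2, 3):
                raise GraphError(f"{path}: malformed line {lineno}: {line!r}")
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise GraphError(f"{path}: bad weight on line {lineno}: {line!r}") from exc
            edges.append((parts[0], parts[1], w))
    if not edges:
        raise GraphError(f"{path}: no edges")
    return Graph.from_edges(edges, nodes=nodes, directed=directed)


def write_edgelist(graph: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# nodes:\t" + "\t".join(graph.node_ids) + "\n")
        fh.write("src\tdst\tweight\n")
        for s, t, w in graph.edges:
            fh.write(f"{s}\t{t}\t{w:.17g}\n")


def read_pajek(path) -> Graph:
    """Read a Pajek ``.net`` file; ``*Arcs`` implies a directed graph."""
    g = nx.read_pajek(path)
    directed = g.is_directed()
    node_ids = tuple(str(v) for v in g.nodes)
    edges = []
    for s, t, data in g.edges(data=True):
        edges.append((str(s), str(t), float(data.get("weight", 1.0))))
    return Graph(node_ids, tuple(edges), directed=directed)


def write_pajek(graph: Graph, path) -> None:
    g = nx.DiGraph() if graph.directed else nx.Graph()
    g.add_nodes_from(graph.node_ids)
    for s, t, w in graph.edges:
        g.add_edge(s, t, weight=w)
    nx.write_pajek(g, path)


def read_graph(path, fmt: str | None = None, directed: bool = False) -> Graph:
    """Dispatch on ``fmt`` (``edgelist`` | ``pajek``), inferred from the suffix."""
    if fmt is None:
        fmt = "pajek" if str(path).endswith(".net") else "edgelist"
    if fmt == "pajek":
        return read_pajek(path)
    if fmt == "edgelist":
        return read_edgelist(path, directed=directed)
    raise GraphError(f"unknown graph format {fmt!r}")


def write_graph(graph: Graph, path, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "pajek" if str(path).endswith(".net") else "edgelist"
    if fmt == "pajek":
        write_pajek(graph, path)
    elif fmt == "edgelist":
        write_edgelist(graph, path)
    else:
        raise GraphError(f"unknown graph format {fmt!r}")


def read_metadata(path, kind: str | None = None) -> MetadataMap:
    """Read node metadata TSV (``node_id  value``).

    Kind inference: all-integer values -> categorical; otherwise numeric ->
    continuous; otherwise the string labels are mapped to integer
    categories in order of first appearance (kept in ``labels``).
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and tuple(p.lower() for p in parts) in {
                ("node_id", "value"), ("node", "value"), ("id", "value")
            }:
                continue
            if len(parts) != 2:
                raise MetadataError(f"{path}: malformed line {lineno}: {line!r}")
            raw[parts[0]] = parts[1]
    if not raw:
        raise MetadataError(f"{path}: no metadata rows")

    def _all(parser) -> bool:
        try:
            for v in raw.values():
                parser(v)
            return True
        except ValueError:
            return False

    if kind == "continuous" or (kind is None and not _all(int) and _all(float)):
        return MetadataMap({k: float(v) for k, v in raw.items()}, "continuous")
    if _all(int):
        return MetadataMap({k: int(v) for k, v in raw.items()}, "categorical")
    mapping: dict[str, int] = {}
    values = {k: mapping.setdefault(v, len(mapping)) for k, v in raw.items()}
    return MetadataMap(values, "categorical", labels={i: s for s, i in mapping.items()})


def write_metadata(meta: MetadataMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tvalue\n")
        for k, v in meta.values.items():
            if meta.kind == "continuous":
                fh.write(f"{k}\t{float(v):.17g}\n")
            else:
                label = meta.labels[int(v)] if meta.labels else int(v)
                fh.write(f"{k}\t{label}\n")


def write_partition(partition: Partition, path, fmt: str = "tsv") -> None:
    """Write a partition as TSV (``node_id  module``) or Pajek ``.clu``
    (1-based module ids, one per node in graph order)."""
    with open(path, "w") as fh:
        if fmt == "clu":
            fh.write(f"*Vertices {len(partition.node_ids)}\n")
            for m in partition.modules:
                fh.write(f"{int(m) + 1}\n")
        elif fmt == "tsv":
            fh.write("node_id\tmodule\n")
            for v, m in zip(partition.node_ids, partition.modules):
                fh.write(f"{v}\t{int(m)}\n")
        else:
            raise MapEqError(f"unknown partition format {fmt!r}")


def read_partition(path, node_ids=None, fmt: str | None = None) -> Partition:
    """Read a partition; ``.clu`` files need ``node_ids`` for the labels."""
    if fmt is None:
        fmt = "clu" if str(path).endswith(".clu") else "tsv"
    if fmt == "clu":
        if node_ids is None:
            raise MapEqError(".clu carries no node ids; pass node_ids")
        mods = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.lower().startswith("*vertices"):
                    continue
                mods.append(int(line) - 1)
        if len(mods) != len(node_ids):
            raise MapEqError(f"{path}: {len(mods)} assignments for {len(node_ids)} nodes")
        return Partition(tuple(node_ids), np.asarray(mods))
    nodes, mods = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and tuple(p.lower() for p in parts) == ("node_id", "module"):
                continue
            if len(parts) != 2:
                raise MapEqError(f"{path}: malformed line {lineno}: {line!r}")
            nodes.append(parts[0])
            mods.append(int(parts[1]))
    return Partition(tuple(nodes), np.asarray(mods))
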