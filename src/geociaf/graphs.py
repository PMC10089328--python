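"""Region adjacency graphs for spatial smoothing.

A :class:`RegionGraph` holds an ordered set of region labels and a symmetric
adjacency relation ("two regions are neighbours if they share a boundary").
It backs the intrinsic GMRF prior on structured spatial effects, whose
precision is the graph Laplacian.

Two on-disk dialects are supported: the ``.gra`` text format used by
spatial-epidemiology tools (line 1: region count; then per region a label
line followed by a line of 0-based neighbour indices) and a JSON object
mapping each region label to its list of neighbour labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = ["RegionGraph", "read_graph", "write_graph"]


@dataclass(frozen=True)
class RegionGraph:
    """Ordered regions plus a symmetric, self-loop-free adjacency."""

    region_ids: tuple[str, ...]
    adjacency: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self):
        ids = tuple(str(r) for r in self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        pairs = set()
        for pair in self.adjacency:
            a, b = tuple(pair)
            if a == b:
                raise ValueError(f"region {a!r} listed as its own neighbour")
            if a not in ids or b not in ids:
                raise ValueError(f"adjacency pair {a!r}-{b!r} references unknown region")
            pairs.add(frozenset((a, b)))
        object.__setattr__(self, "adjacency", frozenset(pairs))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, region: str) -> int:
        return self.region_ids.index(region)

    def neighbors(self, region: str) -> list[str]:
        out = [
            next(iter(p - {region}))
            for p in self.adjacency
            if region in p
        ]
        return sorted(out, key=self.region_ids.index)

    def degree(self, region: str) -> int:
        return sum(1 for p in self.adjacency if region in p)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(tuple(p) for p in self.adjacency)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def require_connected(self) -> "RegionGraph":
        g = self.to_networkx()
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValueError(f"region graph is disconnected; components: {comps}")
        return self


def _read_gra(text: str) -> RegionGraph:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    n = int(lines[0])
    labels: list[str] = []
    neigh_idx: list[list[int]] = []
    pos = 1
    for _ in range(n):
        labels.append(lines[pos])
        neigh_idx.append([int(t) for t in lines[pos + 1].split()] if lines[pos + 1] != "-" else [])
        pos += 2
    return _from_neighbor_lists(labels, [[labels[j] for j in nb] for nb in neigh_idx])


def _from_neighbor_lists(labels: list[str], neigh: list[list[str]]) -> RegionGraph:
    listed: dict[str, set[str]] = {lab: set(nb) for lab, nb in zip(labels, neigh)}
    for a, nbs in listed.items():
        if a in nbs:
            raise ValueError(f"region {a!r} listed as its own neighbour")
        for b in nbs:
            if b not in listed:
                raise ValueError(f"region {a!r} lists unknown neighbour {b!r}")
            if a not in listed[b]:
                raise ValueError(
                    f"asymmetric adjacency: {a!r} lists {b!r} but not vice versa"
                )
    pairs = frozenset(frozenset((a, b)) for a, nbs in listed.items() for b in nbs)
    graph = RegionGraph(tuple(labels), pairs)
    graph.require_connected()
    return graph


def read_graph(path: str | Path) -> RegionGraph:
    """Read a region graph from a ``.gra`` or JSON neighbour-list file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        obj = json.loads(text)
        labels = list(obj)
        return _from_neighbor_lists(labels, [list(map(str, obj[k])) for k in labels])
    return _read_gra(text)


def write_graph(graph: RegionGraph, path: str | Path) -> None:
    """Write a region graph in the dialect implied by the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {r: graph.neighbors(r) for r in graph.region_ids}
        path.write_text(json.dumps(obj, indent=1) + "\n")
        return
    lines = [str(graph.n_regions)]
    pos = {r: i for i, r in enumerate(graph.region_ids)}
    for r in graph.region_ids:
        lines.append(r)
        nbs = [str(pos[t]) for t in graph.neighbors(r)]
        lines.append(" ".join(nbs) if nbs else "-")
    path.write_text("\n".join(lines) + "\n")
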