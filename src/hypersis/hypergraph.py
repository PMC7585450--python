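"""Hypergraph container and plain-text hyperedge-list I/O.

A hypergraph is N nodes plus hyperedges grouped by size m >= 2.  A size-m
hyperedge is a set of m distinct node indices; triangles (m=3) need NOT have
their pairwise links present — this is deliberately not a simplicial-complex
model.  Duplicate hyperedges are allowed and retained: each copy is an
independent contagion channel in the rate model.

File format: one hyperedge per line, whitespace-separated 0-based integer
node ids; ``#`` starts a comment line; an optional first non-comment line
``N <count>`` declares the node count (for isolated nodes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Hypergraph", "read_hyperedge_list", "write_hyperedge_list"]


@dataclass
class Hypergraph:
    """N nodes and hyperedges grouped by size.

    ``edges_by_size[m]`` is an int array of shape (n_edges, m).  Hyperdegrees
    ``k^(m)`` (number of size-m hyperedges containing each node) are computed
    lazily and satisfy the counting identity sum_i k_i^(m) = m * |edges_m|.
    """

    n_nodes: int
    edges_by_size: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nodes < 0:
            raise ValueError("node count must be non-negative")
        clean = {}
        for m, edges in sorted(self.edges_by_size.items()):
            edges = np.asarray(edges, dtype=np.int64).reshape(-1, m)
            if m < 2:
                raise ValueError(f"hyperedge size {m} < 2")
            if edges.size:
                if edges.min() < 0 or edges.max() >= self.n_nodes:
                    raise ValueError(f"size-{m} edge references node outside [0, {self.n_nodes})")
                row_sorted = np.sort(edges, axis=1)
                if np.any(np.diff(row_sorted, axis=1) == 0):
                    raise ValueError(f"size-{m} edge with repeated node")
            clean[m] = edges
        self.edges_by_size = clean

    @property
    def sizes(self) -> list[int]:
        return sorted(self.edges_by_size)

    def num_edges(self, m: int) -> int:
        return 0 if m not in self.edges_by_size else len(self.edges_by_size[m])

    def hyperdegrees(self, m: int) -> np.ndarray:
        """Per-node count of size-m hyperedges, k^(m)."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if m in self.edges_by_size and self.edges_by_size[m].size:
            np.add.at(deg, self.edges_by_size[m].ravel(), 1)
        return deg

    @property
    def links(self) -> np.ndarray:
        return self.edges_by_size.get(2, np.empty((0, 2), dtype=np.int64))

    @property
    def triangles(self) -> np.ndarray:
        return self.edges_by_size.get(3, np.empty((0, 3), dtype=np.int64))

    def merged(self, other: "Hypergraph") -> "Hypergraph":
        """Union of edges (node sets must match)."""
        if other.n_nodes != self.n_nodes:
            raise ValueError("cannot merge hypergraphs with different node counts")
        edges = {m: e.copy() for m, e in self.edges_by_size.items()}
        for m, e in other.edges_by_size.items():
            edges[m] = np.vstack([edges[m], e]) if m in edges else e.copy()
        return Hypergraph(self.n_nodes, edges)


def check_normalization(h: Hypergraph, m: int) -> float:
    """Mean size-m hyperdegree per node, ``<k^(m)> = m |edges_m| / N``.

    The equality with the hyperdegree-sum form is the counting identity that
    fixes the normalization of the wiring probabilities f_m.
    """
    if h.n_nodes == 0:
        return 0.0
    return m * h.num_edges(m) / h.n_nodes


def read_hyperedge_list(path: str | Path | io.TextIOBase) -> Hypergraph:
    """Parse the hyperedge-list text format; N is inferred as 1+max id unless declared."""
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
    else:
        lines = Path(path).read_text().splitlines()
    declared_n: int | None = None
    edges: dict[int, list[list[int]]] = {}
    max_id = -1
    first_data = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if first_data and tokens[0] == "N":
            if len(tokens) != 2:
                raise ValueError(f"line {lineno}: malformed node-count declaration")
            declared_n = int(tokens[1])
            first_data = False
            continue
        first_data = False
        try:
            ids = [int(t) for t in tokens]
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer node id") from None
        if len(ids) < 2:
            raise ValueError(f"line {lineno}: hyperedge of size {len(ids)} < 2")
        if len(set(ids)) != len(ids):
            raise ValueError(f"line {lineno}: duplicate node within hyperedge")
        edges.setdefault(len(ids), []).append(ids)
        max_id = max(max_id, max(ids))
    n = declared_n if declared_n is not None else max_id + 1
    if max_id >= n:
        raise ValueError(f"node id {max_id} exceeds declared N={n}")
    return Hypergraph(n, {m: np.array(e, dtype=np.int64) for m, e in edges.items()})


def write_hyperedge_list(h: Hypergraph, path: str | Path) -> None:
    """Write the hyperedge-list format; round-trips exactly with the reader."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"N {h.n_nodes}\n")
        for m in h.sizes:
            for row in h.edges_by_size[m]:
                fh.write(" ".join(str(int(i)) for i in row) + "\n")
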