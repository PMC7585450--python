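"""Random hypergraph generation matching the mean-field wiring probabilities.

Links follow the configuration-model probability f2(k,k') = k k'/(N<k>).
Triangles (and general size-m hyperedges) are wired either degree-correlated,
with membership probability proportional to the product of the members' link
degrees, or uncorrelated (uniform over node tuples).  The normalization is
chosen so that the mean number of size-m hyperedges per node is a free
parameter (by default equal to <k> for triangles).

The default link generator draws weighted endpoint pairs with the edge count
fixed at round(N<k>/2), which matches f2 in expectation without the
multi-edge/self-loop cleanup of stub matching distorting P(k); exact stub
matching is available for exact degree sequences.  Duplicate hyperedges are
kept (independent contagion channels); members within one hyperedge are
always distinct.
"""

from __future__ import annotations

import logging

import numpy as np

from .hypergraph import Hypergraph, check_normalization

__all__ = [
    "sample_links",
    "sample_triangles",
    "sample_hyperedges_general",
    "check_normalization",
]

log = logging.getLogger(__name__)


def _as_degrees(degrees) -> np.ndarray:
    degrees = np.asarray(degrees, dtype=np.int64)
    if degrees.size == 0:
        raise ValueError("empty degree sequence")
    if np.any(degrees < 0):
        raise ValueError("negative degree")
    return degrees


def _weighted_tuples(rng, weights, count, m):
    """Draw ``count`` m-tuples of distinct nodes with probability ∝ weights.

    Batched rejection: tuples with a repeated member are redrawn, which is a
    vanishing fraction in the sparse regimes used here.
    """
    n = weights.size
    p = weights / weights.sum()
    out = np.empty((count, m), dtype=np.int64)
    filled = 0
    while filled < count:
        batch = max(count - filled, 1000)
        cand = rng.choice(n, size=(batch, m), p=p)
        ok = np.all(np.diff(np.sort(cand, axis=1), axis=1) != 0, axis=1)
        cand = cand[ok][: count - filled]
        out[filled : filled + len(cand)] = cand
        filled += len(cand)
    return out


def sample_links(degrees, seed: int, method: str = "pairs") -> Hypergraph:
    """Generate a size-2-only hypergraph from a link degree sequence.

    method="pairs" (default): round(N<k>/2) edges, endpoints drawn ∝ degree.
    method="stubs": classic stub matching — exact degree sequence up to the
    removal of self-loops (multi-edges retained); an odd stub total is padded
    by one extra stub on node 0.
    """
    degrees = _as_degrees(degrees)
    n = degrees.size
    rng = np.random.default_rng(seed)
    total = int(degrees.sum())
    if total == 0:
        return Hypergraph(n, {2: np.empty((0, 2), dtype=np.int64)})
    if method == "pairs":
        n_edges = int(round(total / 2))
        edges = _weighted_tuples(rng, degrees.astype(np.float64), n_edges, 2)
    elif method == "stubs":
        stubs = np.repeat(np.arange(n), degrees)
        if stubs.size % 2:
            log.warning("odd stub total %d; padding one stub on node 0", stubs.size)
            stubs = np.append(stubs, 0)
        rng.shuffle(stubs)
        edges = stubs.reshape(-1, 2)
        self_loops = edges[:, 0] == edges[:, 1]
        if self_loops.any():
            log.info("dropping %d self-loops from stub matching", int(self_loops.sum()))
            edges = edges[~self_loops]
    else:
        raise ValueError(f"unknown link sampling method {method!r}")
    return Hypergraph(n, {2: edges})


def sample_triangles(degrees, mode: str, mean_q: float, seed: int) -> Hypergraph:
    """Generate a size-3-only hypergraph with ``round(N mean_q / 3)`` triangles.

    mode="correlated": members drawn ∝ link degree (f3 ∝ k k1 k2), so
    high-degree nodes also sit in more triangles.  mode="uncorrelated":
    members uniform over nodes (f3 constant).
    """
    degrees = _as_degrees(degrees)
    n = degrees.size
    if n < 3:
        raise ValueError("need at least 3 nodes for triangles")
    if mean_q < 0:
        raise ValueError("mean_q must be non-negative")
    rng = np.random.default_rng(seed)
    n_tri = int(round(n * mean_q / 3))
    if n_tri == 0:
        return Hypergraph(n, {3: np.empty((0, 3), dtype=np.int64)})
    if mode == "correlated":
        weights = degrees.astype(np.float64)
        if weights.sum() == 0:
            raise ValueError("correlated wiring needs a nonzero degree sequence")
    elif mode == "uncorrelated":
        weights = np.ones(n)
    else:
        raise ValueError(f"unknown wiring mode {mode!r}")
    return Hypergraph(n, {3: _weighted_tuples(rng, weights, n_tri, 3)})


def sample_hyperedges_general(degrees, sizes, mean_km, seed: int) -> Hypergraph:
    """Degree-correlated hyperedges of several sizes.

    For each size m in ``sizes`` with target mean hyperdegree ``mean_km[m]``
    (a mapping, or a sequence aligned with ``sizes``), draws
    round(N * mean_km / m) hyperedges whose members are ∝ link degree —
    the all-sizes generalization of the correlated triangle wiring.
    """
    degrees = _as_degrees(degrees)
    n = degrees.size
    if hasattr(mean_km, "keys"):
        km_map = {int(m): float(mean_km[m]) for m in sizes}
    else:
        km_map = {int(m): float(v) for m, v in zip(sizes, mean_km)}
    rng = np.random.default_rng(seed)
    weights = degrees.astype(np.float64)
    if weights.sum() == 0:
        weights = np.ones(n)
    edges = {}
    for m in sorted(km_map):
        if m < 2:
            raise ValueError(f"hyperedge size {m} < 2")
        if m > n:
            raise ValueError(f"hyperedge size {m} exceeds node count {n}")
        count = int(round(n * km_map[m] / m))
        edges[m] = (
            _weighted_tuples(rng, weights, count, m)
            if count
            else np.empty((0, m), dtype=np.int64)
        )
    return Hypergraph(n, edges)
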