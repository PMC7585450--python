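"""Seeded hypergraph fixtures for tests and demos."""

from __future__ import annotations

from pathlib import Path

from .degrees import make_powerlaw, make_regular
from .generate import sample_links, sample_triangles
from .hypergraph import Hypergraph, write_hyperedge_list

__all__ = ["make_fixture", "build_fixture", "FIXTURES"]


def _powerlaw_hypergraph(n: int, seed: int, wiring: str = "uncorrelated") -> Hypergraph:
    dist = make_powerlaw(4.0, 67, 1000)
    degrees = dist.sample(n, seed)
    links = sample_links(degrees, seed + 1)
    tris = sample_triangles(degrees, wiring, dist.mean, seed + 2)
    return links.merged(tris)


def _regular_links(n: int = 2000, k: int = 100, seed: int = 0) -> Hypergraph:
    degrees = make_regular(k).sample(n, seed)
    return sample_links(degrees, seed + 1, method="stubs")


def _toy_triangle(seed: int = 0) -> Hypergraph:
    import numpy as np

    return Hypergraph(3, {3: np.array([[0, 1, 2]])})


FIXTURES = {
    # N=10^4 power-law r=4 hypergraph with uncorrelated triangles, the
    # configuration behind the hysteresis-sweep figures
    "powerlaw-10k": lambda seed: _powerlaw_hypergraph(10_000, seed),
    "powerlaw-1k": lambda seed: _powerlaw_hypergraph(1_000, seed),
    "regular-links": lambda seed: _regular_links(seed=seed),
    "toy-triangle": _toy_triangle,
}


def build_fixture(name: str, seed: int = 0) -> Hypergraph:
    """Return a preset hypergraph (in memory)."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return factory(seed)


def make_fixture(name: str, seed: int, out_dir: str | Path = ".") -> Path:
    """Write a preset hypergraph to ``<out_dir>/<name>.txt`` and return the path."""
    h = build_fixture(name, seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.txt"
    write_hyperedge_list(h, path)
    return path
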