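"""Degree distributions P(k) over integer support.

The mean-field theory is driven entirely by moments ``<k^n>`` of the
pairwise (link) degree distribution, so distributions are stored as
normalized probability weights on an explicit integer support.  Node
counts P(k) for a network of size N are recovered as ``N * probs``.

Three families cover the standard test cases: truncated power laws
``P(k) ∝ k^-r`` on an inclusive integer range, uniform distributions,
and degenerate (regular-network) distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegreeDistribution",
    "make_powerlaw",
    "make_uniform",
    "make_regular",
    "moment",
    "sample_degrees",
    "PRESETS",
    "from_spec",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability distribution over integer degrees.

    Attributes
    ----------
    support : ndarray of int
        Strictly increasing degrees k >= 0.
    probs : ndarray of float
        Non-negative weights summing to 1.
    label : str
        Free-text provenance, e.g. ``"powerlaw r=4 [67,1000]"``.
    """

    support: np.ndarray
    probs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        if support.ndim != 1 or probs.shape != support.shape:
            raise ValueError("support and probs must be 1-D arrays of equal length")
        if support.size == 0:
            raise ValueError("empty support")
        if np.any(support < 0):
            raise ValueError("degrees must be non-negative")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(probs < 0) or not np.isfinite(probs).all():
            raise ValueError("probabilities must be finite and non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {probs.sum()}, not 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)

    def moment(self, n: int) -> float:
        """Return ``<k^n> = sum_k probs[k] k^n``."""
        if n < 0:
            raise ValueError("moment order must be non-negative")
        return float(np.dot(self.probs, self.support.astype(np.float64) ** n))

    @property
    def mean(self) -> float:
        return self.moment(1)

    def sample(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. degrees; reproducible for a fixed integer seed."""
        if n < 1:
            raise ValueError("sample size must be >= 1")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        return rng.choice(self.support, size=n, p=self.probs)


def make_powerlaw(r: float, kmin: int, kmax: int) -> DegreeDistribution:
    """Truncated power law ``P(k) ∝ k^-r`` on the inclusive range [kmin, kmax]."""
    kmin, kmax = int(kmin), int(kmax)
    if not 0 < kmin <= kmax:
        raise ValueError(f"need 0 < kmin <= kmax, got [{kmin}, {kmax}]")
    k = np.arange(kmin, kmax + 1, dtype=np.float64)
    with np.errstate(over="raise", divide="raise"):
        try:
            w = k ** (-float(r))
        except FloatingPointError as exc:
            raise ValueError(f"non-finite power-law weights for r={r}") from exc
    if not np.isfinite(w).all() or w.sum() == 0:
        raise ValueError(f"non-finite power-law weights for r={r}")
    return DegreeDistribution(k.astype(np.int64), w / w.sum(), f"powerlaw r={r} [{kmin},{kmax}]")


def make_uniform(kmin: int, kmax: int) -> DegreeDistribution:
    """Equal weight on each integer in the inclusive range [kmin, kmax]."""
    kmin, kmax = int(kmin), int(kmax)
    if kmin > kmax:
        raise ValueError(f"need kmin <= kmax, got [{kmin}, {kmax}]")
    k = np.arange(kmin, kmax + 1, dtype=np.int64)
    return DegreeDistribution(k, np.full(k.size, 1.0 / k.size), f"uniform [{kmin},{kmax}]")


def make_regular(k: int) -> DegreeDistribution:
    """Degenerate distribution: every node has degree k."""
    k = int(k)
    if k < 0:
        raise ValueError("degree must be non-negative")
    return DegreeDistribution(np.array([k]), np.array([1.0]), f"regular k={k}")


def moment(dist: DegreeDistribution, n: int) -> float:
    """Moment ``<k^n>`` of a degree distribution (functional form)."""
    return dist.moment(n)


def sample_degrees(dist: DegreeDistribution, n: int, seed: int) -> np.ndarray:
    """Sample a degree sequence of length ``n`` (functional form)."""
    return dist.sample(n, seed)


# The three link-degree distributions used throughout the bistability
# analysis, all calibrated to mean degree ~100.  Strict inequalities in the
# stated ranges ("50<k<150", "67<k<1000", "53<k<1000") are read as exclusive
# bounds, which makes the uniform mean exactly 100.
PRESETS: dict[str, tuple] = {
    "uniform-51-149": (make_uniform, (51, 149)),
    "powerlaw-4-67-1000": (make_powerlaw, (4.0, 67, 1000)),
    "powerlaw-3-53-1000": (make_powerlaw, (3.0, 53, 1000)),
}


def from_spec(spec: dict | str) -> DegreeDistribution:
    """Build a distribution from a config mapping or preset name.

    Mappings use ``{"family": "powerlaw"|"uniform"|"regular", ...}`` with
    family-specific keys ``r``/``kmin``/``kmax``/``k``.
    """
    if isinstance(spec, str):
        try:
            fn, args = PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown preset {spec!r}; available: {sorted(PRESETS)}") from None
        return fn(*args)
    family = spec.get("family")
    if family == "powerlaw":
        return make_powerlaw(spec["r"], spec["kmin"], spec["kmax"])
    if family == "uniform":
        return make_uniform(spec["kmin"], spec["kmax"])
    if family == "regular":
        return make_regular(spec["k"])
    raise ValueError(f"unknown distribution family {family!r}")
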