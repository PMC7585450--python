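"""Onset of bistability: critical triangle infectivity beta3c, the
bistability index B(beta3), and (beta2, beta3) phase diagrams.

Collective triangle contagion opens a bistable window — coexistence of a
stable disease-free state and a stable endemic branch — once the triangle
rate exceeds a critical value beta3c.  Three routes to beta3c are provided:

* ``beta3c_numeric`` — bisection on beta3 of a numerical bistability
  predicate evaluated on the mean-field self-consistency system;
* ``beta3c_analytic_correlated`` — the closed form
  beta3c/gamma = <k^3> <k>^2 / <k^2>^3 for degree-correlated wiring
  (from the slope of the reduced residual at the origin on the critical
  line beta2 = beta2c);
* ``beta3c_analytic_uncorrelated`` — a piecewise expression from the
  quartic expansion h(V, beta2c) = (a0 + a1 V + a2 V^2) V^2 of the coupled
  system: a saddle-node branch (discriminant zero, admissible vertex) when
  one exists, else the transcritical branch gamma <k^3>/<k>^4.

The expansion coefficients below were re-derived symbolically from the
coupled (U, V) equations: U is expanded to second order in V at
beta2 = beta2c by subtracting the two equations (which cancels the
triangle term at first order), substituted into the V-equation, and the
result expanded to fourth order.  The derivation is pinned by two exact
checks: a0 = 0 exactly at beta3 = gamma <k^3>/<k>^4, and the regular
network yields beta3c/beta2c = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .degrees import DegreeDistribution
from .meanfield import (
    EpidemicParams,
    _F_unc,
    count_fixed_points,
    default_grid,
    epidemic_threshold_beta2c,
    find_fixed_points,
    selfconsistency_correlated,
)

__all__ = [
    "ExpansionCoefficients",
    "expansion_coefficients",
    "beta3c_numeric",
    "beta3c_analytic_correlated",
    "beta3c_analytic_uncorrelated",
    "bistability_index",
    "BistabilityCurve",
    "PhaseDiagram",
    "phase_diagram",
    "beta2_scan_grid",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# analytic routes


def beta3c_analytic_correlated(dist: DegreeDistribution, gamma: float) -> float:
    """Closed-form onset for degree-correlated collective contagion:
    beta3c = gamma <k^3> <k>^2 / <k^2>^3."""
    return gamma * dist.moment(3) * dist.moment(1) ** 2 / dist.moment(2) ** 3


@dataclass(frozen=True)
class ExpansionCoefficients:
    """Coefficients of h(V, beta2c) = (a0 + a1 V + a2 V^2) V^2 for the
    uncorrelated collective system."""

    a0: float
    a1: float
    a2: float

    @property
    def vertex(self) -> float:
        """Location -a1/(2 a2) of the quadratic's extremum."""
        return -self.a1 / (2 * self.a2)


def _coeff_polys(dist: DegreeDistribution, gamma: float):
    """a0, a1, a2 as polynomial coefficient arrays in beta3 (ascending)."""
    g = gamma
    m1, m2, m3, m4, m5 = (dist.moment(n) for n in range(1, 6))
    a0 = np.array([-m1 * m3 / m2**2, m1**5 / (g * m2**2)])
    a1 = np.array(
        [m1**2 * m4 / m2**3, -4 * m1**5 / (g * m2**2) + 2 * m1**4 * m3 / (g * m2**3)]
    )
    a2 = np.array(
        [
            -(m1**3) * m5 / m2**4,
            5 * m1**5 / (g * m2**2)
            + 3 * m1**6 * m3 / (g * m2**4)
            - 6 * m1**4 * m3 / (g * m2**3)
            + m1**3 * m3**2 / (g * m2**4),
            -(m1**10) / (g**2 * m2**4),
        ]
    )
    return a0, a1, a2


def expansion_coefficients(
    dist: DegreeDistribution, gamma: float, beta3: float
) -> ExpansionCoefficients:
    """Evaluate the quartic-expansion coefficients at a given beta3."""
    a0, a1, a2 = _coeff_polys(dist, gamma)
    ev = lambda c: float(np.polynomial.polynomial.polyval(beta3, c))
    return ExpansionCoefficients(ev(a0), ev(a1), ev(a2))


def beta3c_analytic_uncorrelated(dist: DegreeDistribution, gamma: float) -> float:
    """Piecewise closed-form onset for uncorrelated collective contagion.

    Solve a1^2 - 4 a0 a2 = 0 for beta3 (a cubic); a root is admissible when
    a2 < 0 and the quadratic's vertex -a1/(2 a2) lies in [0, 1] (the
    saddle-node must be born inside the physical interval).  The smallest
    admissible root is the onset; with no admissible root the onset is the
    transcritical value gamma <k^3>/<k>^4.
    """
    import numpy.polynomial.polynomial as P

    a0, a1, a2 = _coeff_polys(dist, gamma)
    disc = P.polysub(P.polymul(a1, a1), 4 * P.polymul(a0, a2))
    roots = np.roots(disc[::-1])
    candidates = []
    for r in roots:
        if abs(r.imag) > 1e-10 * max(1.0, abs(r.real)) or r.real <= 0:
            continue
        b3 = float(r.real)
        c = ExpansionCoefficients(
            float(P.polyval(b3, a0)), float(P.polyval(b3, a1)), float(P.polyval(b3, a2))
        )
        if c.a2 < 0 and 0 <= c.vertex <= 1:
            candidates.append(b3)
    if candidates:
        return min(candidates)
    return gamma * dist.moment(3) / dist.moment(1) ** 4


# ---------------------------------------------------------------------------
# numerical route


def beta2_scan_grid(beta2c: float, n: int = 61) -> np.ndarray:
    """beta2 grid for multiplicity detection, concentrated just below
    beta2c where saddle-node pairs are born."""
    n1 = n // 3
    lo = np.linspace(0.5 * beta2c, 0.9 * beta2c, n1, endpoint=False)
    hi = np.linspace(0.9 * beta2c, 1.02 * beta2c, n - n1)
    return np.concatenate([lo, hi])


def _bistable_critical_line(dist, gamma, beta3, wiring, grid) -> bool:
    """Bistability predicate evaluated on the critical line beta2 = beta2c.

    The reduced residual is monotone in beta2 and vanishes at the origin at
    beta2c, so a positive excursion at some V > 0 (resp. U > 0) on the
    critical line is equivalent, by continuity, to the existence of three
    fixed points for beta2 slightly below beta2c.
    """
    b2c = epidemic_threshold_beta2c(dist, gamma)
    params = EpidemicParams(gamma=gamma, beta2=b2c, beta3=beta3, rule="collective", wiring=wiring)
    pos = grid[grid > 0]
    if wiring == "correlated":
        res = selfconsistency_correlated(pos, dist, params)
    else:
        res, _ = _F_unc(pos, dist, params)
    return bool(res.max() > 0)


def _bistable_count(dist, gamma, beta3, wiring, grid) -> bool:
    """Literal predicate: three fixed points at some beta2 on the scan grid."""
    b2c = epidemic_threshold_beta2c(dist, gamma)
    for b2 in beta2_scan_grid(b2c):
        params = EpidemicParams(
            gamma=gamma, beta2=b2, beta3=beta3, rule="collective", wiring=wiring
        )
        if count_fixed_points(dist, params, grid) >= 3:
            return True
    return False


def beta3c_numeric(
    dist: DegreeDistribution,
    gamma: float,
    wiring: str = "correlated",
    rule: str = "collective",
    method: str = "critical",
    rtol: float = 1e-4,
    grid: np.ndarray | None = None,
) -> float:
    """Numerical onset of bistability by bisection on beta3.

    ``method="critical"`` (default) bisects the critical-line predicate;
    ``method="grid"`` bisects the count-of-roots predicate over a beta2 scan
    grid (slower and biased upward by the narrowness of the bistable window
    near onset, but independent of the continuity argument).
    """
    if rule != "collective":
        raise ValueError("bistability onset is analyzed for the collective rule")
    if grid is None:
        grid = default_grid()
    predicate = {"critical": _bistable_critical_line, "grid": _bistable_count}[method]
    lo = 0.0
    if predicate(dist, gamma, 0.0, wiring, grid):
        raise RuntimeError("bistability predicate already true at beta3 = 0")
    hi = 3.0 * beta3c_analytic_correlated(dist, gamma)
    for _ in range(8):
        if predicate(dist, gamma, hi, wiring, grid):
            break
        lo, hi = hi, 2 * hi
    else:
        raise RuntimeError(f"no bistability found up to beta3 = {hi}")
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if predicate(dist, gamma, mid, wiring, grid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# bistability index and phase diagram


@dataclass
class BistabilityCurve:
    beta3_grid: np.ndarray
    B: np.ndarray
    beta3c: float  # onset estimate: first grid point with B above threshold

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"beta3": self.beta3_grid, "B": self.B})


def bistability_index(
    dist: DegreeDistribution,
    gamma: float,
    beta3: float,
    wiring: str = "correlated",
    rule: str = "collective",
    beta2_grid: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """Bistability index B: the maximum separation, over beta2, between the
    largest and smallest stable equilibrium prevalence U (the disease-free
    state counts when stable)."""
    b2c = epidemic_threshold_beta2c(dist, gamma)
    if beta2_grid is None:
        beta2_grid = np.linspace(0.5 * b2c, 1.5 * b2c, 201)
    best = 0.0
    for b2 in beta2_grid:
        params = EpidemicParams(
            gamma=gamma, beta2=float(b2), beta3=beta3, rule=rule, wiring=wiring
        )
        stable = find_fixed_points(dist, params, grid).stable_U
        if stable.size >= 2:
            best = max(best, float(stable.max() - stable.min()))
    return best


def bistability_curve(
    dist: DegreeDistribution,
    gamma: float,
    beta3_grid: np.ndarray,
    wiring: str = "correlated",
    rule: str = "collective",
    beta2_grid: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    onset_threshold: float = 1e-3,
) -> BistabilityCurve:
    """B(beta3) on a grid, with the onset read off the curve."""
    B = np.array(
        [
            bistability_index(dist, gamma, float(b3), wiring, rule, beta2_grid, grid)
            for b3 in beta3_grid
        ]
    )
    above = np.nonzero(B > onset_threshold)[0]
    onset = float(beta3_grid[above[0]]) if above.size else float("nan")
    return BistabilityCurve(np.asarray(beta3_grid, dtype=float), B, onset)


@dataclass
class PhaseDiagram:
    beta2_grid: np.ndarray
    beta3_grid: np.ndarray
    counts: np.ndarray  # shape (len(beta3_grid), len(beta2_grid))

    def to_frame(self):
        import pandas as pd

        b2, b3 = np.meshgrid(self.beta2_grid, self.beta3_grid)
        return pd.DataFrame(
            {"beta2": b2.ravel(), "beta3": b3.ravel(), "count": self.counts.ravel()}
        )


def phase_diagram(
    dist: DegreeDistribution,
    gamma: float,
    beta2_grid: np.ndarray | None = None,
    beta3_grid: np.ndarray | None = None,
    wiring: str = "correlated",
    rule: str = "collective",
    triangle_sign: str = "contagion",
    grid: np.ndarray | None = None,
) -> PhaseDiagram:
    """Solution counts of the self-consistency system on a (beta2, beta3)
    grid: 1 = no infection, 2 = endemic state, 3 = bistability.

    Default grids cover [0, 2 beta2c] x [0, 3 beta3c_analytic]; for the
    individual rule with higher-order healing, where the bistable band sits
    near the shifted threshold beta2 ~ beta2c + 2 beta3, the default beta2
    range is extended to cover it.
    """
    b2c = epidemic_threshold_beta2c(dist, gamma)
    b3ref = beta3c_analytic_correlated(dist, gamma)
    if beta3_grid is None:
        beta3_grid = np.linspace(0.0, 3.0 * b3ref, 101)
    if beta2_grid is None:
        hi = 2.0 * b2c
        if triangle_sign == "healing" and rule == "individual":
            hi = 1.2 * (b2c + 2.0 * float(np.max(beta3_grid)))
        beta2_grid = np.linspace(0.0, hi, 101)
    if grid is None:
        grid = default_grid(1201)
    counts = np.empty((len(beta3_grid), len(beta2_grid)), dtype=np.int64)
    for i, b3 in enumerate(beta3_grid):
        for j, b2 in enumerate(beta2_grid):
            params = EpidemicParams(
                gamma=gamma,
                beta2=float(b2),
                beta3=float(b3),
                rule=rule,
                wiring=wiring,
                triangle_sign=triangle_sign,
            )
            counts[i, j] = count_fixed_points(dist, params, grid)
    return PhaseDiagram(np.asarray(beta2_grid, float), np.asarray(beta3_grid, float), counts)
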