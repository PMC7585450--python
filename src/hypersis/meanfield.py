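"""Hyperdegree mean-field dynamics and steady-state analysis.

The theory tracks x_k, the fraction of infected nodes in each link-degree
class k, closed under the assumption that node states are independent within
degree classes.  Two global order parameters appear:

    U = sum_k P(k) x_k / N          (fraction of infected nodes)
    V = sum_k k P(k) x_k / (N <k>)  (fraction of infected link ends)

For links+triangles hypergraphs the local infection pressure on class k is

    correlated wiring:    A_k = k V s(V)
    uncorrelated wiring:  A_k = beta2 k V + sigma beta3 <k> T(U)

where s(V) collects the rule-dependent triangle terms (collective:
beta2 + sigma beta3 V; individual: beta2 + sigma(2 beta3 - beta3 V)) and
T(U) = U^2 (collective) or 2U - U^2 (individual); sigma = +-1 selects
triangle contagion vs higher-order healing.  Steady states satisfy
x_k = A_k/(gamma + A_k), which reduces to a scalar self-consistency equation
in V (correlated) or a coupled (U, V) system (uncorrelated).

With the healing sign, A_k can be negative, in which case the algebraic
fixed point x_k = A_k/(gamma+A_k) leaves [0,1] and is not a physical
equilibrium; root counting is restricted to the region where all x_k lie in
[0,1] (equivalently s(V) >= 0, resp. min_k A_k >= 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .degrees import DegreeDistribution
from .params import EpidemicParams

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "MeanFieldTrajectory",
    "rhs_general",
    "integrate_meanfield",
    "selfconsistency_correlated",
    "selfconsistency_uncorrelated",
    "find_fixed_points",
    "epidemic_threshold_beta2c",
    "threshold_individual",
    "threshold_multisize",
]

log = logging.getLogger(__name__)

MERGE_TOL = 1e-6  # roots closer than this in V are considered one root


def default_grid(n: int = 1601) -> np.ndarray:
    """Scan grid on [0, 1], geometrically dense near 0 where saddle-node
    pairs are born, with a uniform backbone."""
    geo = np.geomspace(1e-8, 0.05, n // 2)
    uni = np.linspace(0.05, 1.0, n - n // 2)
    return np.concatenate([[0.0], geo, uni])


# ---------------------------------------------------------------------------
# local infection pressure


def _s_factor(params: EpidemicParams, V):
    """Correlated-case scalar factor: A_k = k V s(V)."""
    b2, b3, sg = params.beta2, params.beta3, params.sign
    if params.rule == "collective":
        return b2 + sg * b3 * V
    return b2 + sg * (2 * b3 - b3 * V)


def _tri_pressure_unc(params: EpidemicParams, U):
    """Uncorrelated-case triangle term (without the <k> factor)."""
    b3, sg = params.beta3, params.sign
    if params.rule == "collective":
        return sg * b3 * U * U
    return sg * b3 * (2 * U - U * U)


def _xk(A, gamma):
    return A / (gamma + A)


# ---------------------------------------------------------------------------
# residuals


def selfconsistency_correlated(V, dist: DegreeDistribution, params: EpidemicParams):
    """Residual h(V) of the degree-correlated self-consistency equation.

    h(V) = (1/<k>) sum_k p_k k A_k/(gamma+A_k) - V with A_k = k V s(V).
    Roots of h on the physically valid region (s(V) >= 0) are equilibria.
    Accepts scalar or array V; vectorized over V.
    """
    scalar = np.asarray(V).ndim == 0
    Varr = np.atleast_1d(np.asarray(V, dtype=float))
    k = dist.support.astype(float)
    p = dist.probs
    s = _s_factor(params, Varr)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = k[None, :] * (Varr * s)[:, None]
        h = (p * k * _xk(A, params.gamma)).sum(axis=1) / dist.mean - Varr
    return float(h[0]) if scalar else h


def _corr_valid(V, params: EpidemicParams):
    return np.asarray(_s_factor(params, np.asarray(V, dtype=float))) >= 0


def selfconsistency_uncorrelated(U, V, dist: DegreeDistribution, params: EpidemicParams):
    """Residual pair (resU, resV) of the uncorrelated coupled system."""
    k = dist.support.astype(float)
    p = dist.probs
    kbar = dist.mean
    A = params.beta2 * k * V + kbar * _tri_pressure_unc(params, U)
    x = _xk(A, params.gamma)
    return float((p * x).sum() - U), float((p * k * x).sum() / kbar - V)


def _solve_V_given_U(U, dist, params, iters: int = 60):
    """Vectorized bisection for the unique V solving the V-equation at fixed U.

    For contagion-sign models the V-residual at V=0 is >= 0 and the RHS is
    concave increasing in V, so there is exactly one root for U > 0.
    """
    U = np.atleast_1d(np.asarray(U, dtype=float))
    k = dist.support.astype(float)[None, :]
    p = dist.probs[None, :]
    kbar = dist.mean
    c = kbar * _tri_pressure_unc(params, U)[:, None]

    def phi(V):
        A = params.beta2 * k * V[:, None] + c
        return (p * k * _xk(A, params.gamma)).sum(axis=1) / kbar - V

    lo = np.zeros_like(U)
    hi = np.ones_like(U)
    hi_val = phi(hi)
    at_one = hi_val >= 0  # degenerate: root pinned at 1
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos = phi(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    V = 0.5 * (lo + hi)
    return np.where(at_one, 1.0, V)


def _F_unc(U, dist, params):
    """Reduced scalar residual F(U) after eliminating V; roots on (0,1] are
    the nonzero equilibria of the coupled system."""
    U = np.atleast_1d(np.asarray(U, dtype=float))
    V = _solve_V_given_U(U, dist, params)
    k = dist.support.astype(float)[None, :]
    p = dist.probs[None, :]
    A = params.beta2 * k * V[:, None] + dist.mean * _tri_pressure_unc(params, U)[:, None]
    F = (p * _xk(A, params.gamma)).sum(axis=1) - U
    return F, V


# ---------------------------------------------------------------------------
# thresholds


def epidemic_threshold_beta2c(dist: DegreeDistribution, gamma: float) -> float:
    """Pairwise epidemic threshold beta2c = gamma <k>/<k^2> (both wirings)."""
    m2 = dist.moment(2)
    if m2 == 0:
        raise ValueError("degenerate distribution: <k^2> = 0")
    return gamma * dist.moment(1) / m2


def threshold_individual(
    dist: DegreeDistribution,
    gamma: float,
    beta3: float,
    wiring: str = "correlated",
    triangle_sign: str = "contagion",
) -> float:
    """Critical beta2 for the individual-contagion rule.

    Correlated: beta2 = gamma <k>/<k^2> - 2 beta3 (linear trade-off between
    link and triangle channels).  Uncorrelated: the nonlinear relation

        beta2 = (<k> gamma^2 - 2 <k>^2 gamma beta3)
                / (<k^2> gamma - 2 (<k^2> - <k>^2) <k> beta3).

    ``triangle_sign="healing"`` substitutes -beta3.  A negative return value
    is reported as-is (and logged as non-physical): the disease-free state is
    then unstable for every beta2 >= 0.
    """
    b3 = beta3 if triangle_sign == "contagion" else -beta3
    m1, m2 = dist.moment(1), dist.moment(2)
    if wiring == "correlated":
        b2 = gamma * m1 / m2 - 2 * b3
    elif wiring == "uncorrelated":
        den = m2 * gamma - 2 * (m2 - m1**2) * m1 * b3
        if den == 0:
            # pole at beta3* = gamma <k^2> / (2 (<k^2>-<k>^2) <k>); the branch
            # crosses zero before the pole, so it carries no physical threshold
            raise ZeroDivisionError(
                "beta3 sits at the singularity of the uncorrelated threshold; "
                "beta2 is negative there, so the pole is not physically relevant"
            )
        b2 = (m1 * gamma**2 - 2 * m1**2 * gamma * b3) / den
    else:
        raise ValueError(f"unknown wiring {wiring!r}")
    if b2 < 0:
        log.warning("critical beta2 = %g < 0 (non-physical; 0-state unstable for all beta2>=0)", b2)
    return float(b2)


def threshold_multisize(dist: DegreeDistribution, gamma: float, beta_m: dict, mean_km: dict):
    """Propagation condition for the all-sizes, degree-correlated,
    individual-contagion model.

    Returns ``(lhs, rhs, propagates)`` where
    lhs = sum_m (m-1) beta_m <k^(m)>/<k> and rhs = gamma <k>/<k^2>;
    contagion propagates when lhs > rhs.
    """
    kbar = dist.mean
    lhs = sum((m - 1) * beta_m[m] * mean_km[m] / kbar for m in beta_m)
    rhs = gamma * kbar / dist.moment(2)
    return float(lhs), float(rhs), bool(lhs > rhs)


# ---------------------------------------------------------------------------
# fixed points


@dataclass(frozen=True)
class FixedPoint:
    V: float
    U: float
    x_k: np.ndarray
    stable: bool


@dataclass
class FixedPointSet:
    """Equilibria of the self-consistency system, origin first."""

    roots: list[FixedPoint]
    params: EpidemicParams
    dist_label: str = ""

    def __len__(self) -> int:
        return len(self.roots)

    @property
    def stable_U(self) -> np.ndarray:
        return np.array([r.U for r in self.roots if r.stable])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "V": [r.V for r in self.roots],
                "U": [r.U for r in self.roots],
                "stability": ["stable" if r.stable else "unstable" for r in self.roots],
            }
        )


def _origin_stable(dist: DegreeDistribution, params: EpidemicParams) -> bool:
    """Stability of the disease-free state from the linearization."""
    g = params.gamma
    m1, m2 = dist.moment(1), dist.moment(2)
    if params.rule == "collective":
        # triangle terms are quadratic near 0 in both wirings
        return params.beta2 < g * m1 / m2
    sg = params.sign
    if params.wiring == "correlated":
        return params.beta2 + 2 * sg * params.beta3 < g * m1 / m2
    # uncorrelated individual: 2x2 Jacobian on (dU, dV)
    J = np.array(
        [
            [-g + 2 * sg * params.beta3 * m1, params.beta2 * m1],
            [2 * sg * params.beta3 * m1, -g + params.beta2 * m2 / m1],
        ]
    )
    return float(np.linalg.eigvals(J).real.max()) < 0


def _sign_change_roots(grid, res, valid, fn):
    """Bracketed sign changes of ``res`` on ``grid`` within valid segments,
    polished by brentq on the scalar callable ``fn``."""
    roots = []
    s = np.sign(res)
    for i in range(len(grid) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        if s[i] == 0 and grid[i] > 0:
            roots.append(grid[i])
        elif s[i] * s[i + 1] < 0:
            try:
                roots.append(brentq(fn, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-14))
            except ValueError:  # pragma: no cover - bracket lost to noise
                log.warning("bracket [%g, %g] could not be polished", grid[i], grid[i + 1])
    merged = []
    for r in sorted(roots):
        if r <= MERGE_TOL:
            continue  # belongs to the origin root
        if not merged or r - merged[-1] > MERGE_TOL:
            merged.append(r)
    return merged


def find_fixed_points(
    dist: DegreeDistribution,
    params: EpidemicParams,
    grid: np.ndarray | None = None,
) -> FixedPointSet:
    """All equilibria in [0,1], with stability labels.

    The disease-free state is always included.  Interior roots are located by
    a dense scan for sign changes (restricted to the physically valid region
    where every x_k lies in [0,1]) polished by bisection; stability of
    interior roots follows the sign of the residual slope, and of the origin
    the linearization of the dynamics.
    """
    if grid is None:
        grid = default_grid()
    k = dist.support.astype(float)
    p = dist.probs
    g = params.gamma
    roots: list[FixedPoint] = [
        FixedPoint(0.0, 0.0, np.zeros_like(k), _origin_stable(dist, params))
    ]

    if params.wiring == "correlated":
        res = selfconsistency_correlated(grid, dist, params)
        valid = _corr_valid(grid, params)
        fn = lambda v: selfconsistency_correlated(v, dist, params)
        for V in _sign_change_roots(grid, res, valid, fn):
            A = k * V * _s_factor(params, V)
            x = _xk(A, g)
            U = float((p * x).sum())
            dh = (fn(min(V + 1e-7, 1.0)) - fn(max(V - 1e-7, 0.0)))
            roots.append(FixedPoint(float(V), U, x, bool(dh < 0)))
    else:
        if params.triangle_sign == "healing":
            raise NotImplementedError(
                "fixed-point enumeration for uncorrelated wiring with "
                "higher-order healing is not supported; the epidemic threshold "
                "is available via threshold_individual"
            )
        ugrid = grid[grid > 0]
        F, _ = _F_unc(ugrid, dist, params)
        valid = np.ones(ugrid.size, dtype=bool)
        fn = lambda u: float(_F_unc(u, dist, params)[0][0])
        for U in _sign_change_roots(ugrid, F, valid, fn):
            V = float(_solve_V_given_U(U, dist, params)[0])
            A = params.beta2 * k * V + dist.mean * _tri_pressure_unc(params, U)
            x = _xk(A, g)
            dF = fn(min(U + 1e-7, 1.0)) - fn(max(U - 1e-7, 0.0))
            roots.append(FixedPoint(V, float(U), x, bool(dF < 0)))

    return FixedPointSet(roots, params, dist.label)


def count_fixed_points(
    dist: DegreeDistribution, params: EpidemicParams, grid: np.ndarray | None = None
) -> int:
    """Number of equilibria (origin included) — the phase-diagram quantity."""
    return len(find_fixed_points(dist, params, grid))


# ---------------------------------------------------------------------------
# dynamics


def rhs_general(x, dist: DegreeDistribution, params: EpidemicParams) -> np.ndarray:
    """Time derivative of the per-degree-class infected fractions.

    Covers the links+triangles models in all four structure x rule
    combinations (with either triangle sign) and, when ``params.beta_m`` is
    set, the all-sizes degree-correlated model

        dx_k/dt = -gamma x_k
                  + k (1-x_k) sum_m beta_m (<k^(m)>/<k>) G_m(V),

    with G_m(V) = V^(m-1) for collective contagion and 1-(1-V)^(m-1) for
    individual contagion.  Derivatives are projected so that trajectories
    cannot leave [0, 1]^n.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    k = dist.support.astype(float)
    p = dist.probs
    kbar = dist.mean
    V = float((p * k * x).sum() / kbar)
    if params.beta_m is not None:
        if params.mean_km is None:
            raise ValueError("all-sizes model needs mean_km alongside beta_m")
        pressure = 0.0
        for m, bm in params.beta_m.items():
            Gm = V ** (m - 1) if params.rule == "collective" else 1 - (1 - V) ** (m - 1)
            pressure += bm * params.mean_km[m] / kbar * Gm
        A = k * pressure
    elif params.wiring == "correlated":
        A = k * V * _s_factor(params, V)
    else:
        U = float((p * x).sum())
        A = params.beta2 * k * V + kbar * _tri_pressure_unc(params, U)
    d = -params.gamma * x + (1 - x) * A
    d = np.where((x <= 0) & (d < 0), 0.0, d)
    d = np.where((x >= 1) & (d > 0), 0.0, d)
    return d


@dataclass
class MeanFieldTrajectory:
    t: np.ndarray
    x: np.ndarray  # shape (n_times, n_classes)
    U: np.ndarray
    V: np.ndarray
    converged: bool


def integrate_meanfield(
    dist: DegreeDistribution,
    params: EpidemicParams,
    x0,
    t_end: float,
    n_eval: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dxdt_tol: float = 1e-10,
) -> MeanFieldTrajectory:
    """Integrate the mean-field ODE from initial class fractions ``x0``.

    ``x0`` may be a scalar (uniform initial fraction) or a vector over the
    support.  Integration stops early once ``max|dx/dt| < dxdt_tol``
    (declared convergence to a fixed point).
    """
    k = dist.support
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim == 0:
        x0 = np.full(k.size, float(x0))
    if x0.shape != (k.size,):
        raise ValueError("x0 must be scalar or match the support length")
    if np.any((x0 < 0) | (x0 > 1)):
        raise ValueError("x0 components must lie in [0, 1]")

    def f(t, x):
        return rhs_general(x, dist, params)

    def settled(t, x):
        return float(np.abs(rhs_general(x, dist, params)).max() - dxdt_tol)

    settled.terminal = True
    settled.direction = -1

    sol = solve_ivp(
        f,
        (0.0, t_end),
        x0,
        method="RK45",
        t_eval=np.linspace(0.0, t_end, n_eval),
        events=settled,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    x = np.clip(sol.y.T, 0.0, 1.0)
    t = sol.t
    if sol.t_events[0].size:  # append the converged end state
        t = np.append(t, sol.t_events[0][0])
        x = np.vstack([x, np.clip(sol.y_events[0][0], 0.0, 1.0)])
    if not np.isfinite(x).all():
        raise RuntimeError("non-finite mean-field state encountered")
    p = dist.probs
    kf = k.astype(float)
    U = x @ p
    V = x @ (p * kf) / dist.mean
    return MeanFieldTrajectory(t, x, U, V, converged=bool(sol.t_events[0].size))
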