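"""Exact stochastic simulation of SIS contagion on hypergraphs.

The dynamics is a continuous-time Markov chain sampled exactly with a
rejection-free Gillespie scheme.  Per-node total rates (healing plus all
eligible hyperedge channels) are kept in a Fenwick tree for O(log N)
sampling; eligibility counters per hyperedge are updated incrementally on
every state flip, so an event costs O(incident hyperedges * log N).

Channels, per hyperedge of size m with rate beta_m:

* collective contagion — the single susceptible member is infected at rate
  beta_m when all m-1 others are infected;
* individual contagion — every susceptible member with at least one
  infected co-member is infected at rate beta_m;
* higher-order healing (triangles) — the rule's condition is kept but the
  action recovers infected members at rate beta3 instead.

Healing of infected nodes at rate gamma runs independently of everything.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .hypergraph import Hypergraph
from .params import EpidemicParams

__all__ = ["SimTrajectory", "SweepResult", "simulate_sis", "hysteresis_sweep", "bistability_index_sim"]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# jitted core


@njit(cache=True, inline="always")
def _fw_update(tree, i, delta):
    i += 1
    while i < tree.shape[0]:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fw_build(rate):
    n = rate.shape[0]
    tree = np.zeros(n + 1)
    for i in range(n):
        _fw_update(tree, i, rate[i])
    return tree


@njit(cache=True, inline="always")
def _fw_find(tree, r, top):
    """Largest index with prefix sum < r; returns the 0-based node index."""
    idx = 0
    bit = top
    while bit:
        nxt = idx + bit
        if nxt < tree.shape[0] and tree[nxt] < r:
            idx = nxt
            r -= tree[nxt]
        bit >>= 1
    return idx


@njit(cache=True, inline="always")
def _cond(others, size, collective):
    if collective:
        return others == size - 1
    return others >= 1


@njit(cache=True)
def _gillespie(
    n,
    inc_indptr,
    inc_ids,
    he_offsets,
    he_nodes,
    he_beta,
    he_healing,
    he_collective,
    infected,
    gamma,
    t_end,
    record_dt,
    avg_from,
    seed,
):
    """Run the chain on [0, t_end]; mutates ``infected`` in place.

    Returns (rec_t, rec_U, avg_U, n_events) where rec_* sample the
    prevalence every record_dt and avg_U is the time-averaged prevalence
    over [avg_from, t_end].
    """
    np.random.seed(seed)
    n_he = he_offsets.shape[0] - 1

    # eligibility counters
    c = np.zeros(n_he, dtype=np.int64)
    for e in range(n_he):
        for a in range(he_offsets[e], he_offsets[e + 1]):
            c[e] += infected[he_nodes[a]]
    w = np.zeros(n)   # summed contagion-channel rates per node
    wh = np.zeros(n)  # summed healing-channel rates per node
    for i in range(n):
        for a in range(inc_indptr[i], inc_indptr[i + 1]):
            e = inc_ids[a]
            size = he_offsets[e + 1] - he_offsets[e]
            if _cond(c[e] - infected[i], size, he_collective[e]):
                if he_healing[e]:
                    wh[i] += he_beta[e]
                else:
                    w[i] += he_beta[e]

    rate = np.empty(n)
    n_inf = 0
    for i in range(n):
        if infected[i]:
            rate[i] = gamma + wh[i]
            n_inf += 1
        else:
            rate[i] = w[i]
    tree = _fw_build(rate)
    total = rate.sum()
    top = 1
    while top * 2 <= n:
        top *= 2

    n_rec = int(math.floor(t_end / record_dt)) + 1
    rec_t = np.empty(n_rec)
    rec_U = np.empty(n_rec)
    rec_i = 0
    t = 0.0
    avg_acc = 0.0
    n_events = 0

    while True:
        if total <= 1e-12:
            t_new = t_end
        else:
            t_new = t - math.log(np.random.random()) / total
        # record prevalence on [t, t_new)
        while rec_i < n_rec and rec_i * record_dt <= t_new:
            rec_t[rec_i] = rec_i * record_dt
            rec_U[rec_i] = n_inf / n
            rec_i += 1
        lo = t if t > avg_from else avg_from
        hi = t_new if t_new < t_end else t_end
        if hi > lo:
            avg_acc += (hi - lo) * n_inf
        t = t_new
        if t >= t_end or total <= 1e-12:
            break

        r = np.random.random() * total
        j = _fw_find(tree, r, top)
        old_inf = infected[j]
        d = -1 if old_inf else 1
        infected[j] = 1 - old_inf
        n_inf += d
        n_events += 1

        # update counters of co-members, then refresh touched rates
        for a in range(inc_indptr[j], inc_indptr[j + 1]):
            e = inc_ids[a]
            size = he_offsets[e + 1] - he_offsets[e]
            old_c = c[e]
            c[e] += d
            for b in range(he_offsets[e], he_offsets[e + 1]):
                u = he_nodes[b]
                if u == j:
                    continue
                o_old = old_c - infected[u]
                was = _cond(o_old, size, he_collective[e])
                now = _cond(o_old + d, size, he_collective[e])
                if was != now:
                    delta = he_beta[e] if now else -he_beta[e]
                    if he_healing[e]:
                        wh[u] += delta
                    else:
                        w[u] += delta
        newr = gamma + wh[j] if infected[j] else w[j]
        if newr < 0.0:
            newr = 0.0
        diff = newr - rate[j]
        if diff != 0.0:
            _fw_update(tree, j, diff)
            total += diff
            rate[j] = newr
        for a in range(inc_indptr[j], inc_indptr[j + 1]):
            e = inc_ids[a]
            for b in range(he_offsets[e], he_offsets[e + 1]):
                u = he_nodes[b]
                newr = gamma + wh[u] if infected[u] else w[u]
                if newr < 0.0:
                    newr = 0.0
                diff = newr - rate[u]
                if diff != 0.0:
                    _fw_update(tree, u, diff)
                    total += diff
                    rate[u] = newr
        if n_events % 1048576 == 0:  # refresh against float drift
            for i in range(n):
                rate[i] = gamma + wh[i] if infected[i] else w[i]
            tree = _fw_build(rate)
            total = rate.sum()

    while rec_i < n_rec:
        rec_t[rec_i] = rec_i * record_dt
        rec_U[rec_i] = n_inf / n
        rec_i += 1
    span = t_end - avg_from
    avg_U = avg_acc / (n * span) if span > 0 else n_inf / n
    return rec_t, rec_U, avg_U, n_events


# ---------------------------------------------------------------------------
# python surface


def _build_arrays(h: Hypergraph, params: EpidemicParams):
    """Flatten hyperedges (all sizes) and build node->edge incidence."""
    betas = dict(params.beta_m) if params.beta_m else {}
    if 2 not in betas:
        betas[2] = params.beta2
    if 3 not in betas:
        betas[3] = params.beta3
    chunks, beta_list, heal_list = [], [], []
    for m in h.sizes:
        edges = h.edges_by_size[m]
        if not len(edges):
            continue
        chunks.append(edges)
        bm = betas.get(m, 0.0)
        beta_list.append(np.full(len(edges), float(bm)))
        heal_list.append(
            np.full(len(edges), params.triangle_sign == "healing" and m == 3, dtype=np.bool_)
        )
    if chunks:
        sizes = np.concatenate([np.full(len(ch), ch.shape[1], dtype=np.int64) for ch in chunks])
        he_nodes = np.concatenate([ch.ravel() for ch in chunks])
        he_beta = np.concatenate(beta_list)
        he_healing = np.concatenate(heal_list)
    else:
        sizes = np.empty(0, dtype=np.int64)
        he_nodes = np.empty(0, dtype=np.int64)
        he_beta = np.empty(0)
        he_healing = np.empty(0, dtype=np.bool_)
    he_offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
    he_collective = np.full(sizes.shape[0], params.rule == "collective", dtype=np.bool_)
    # links behave identically under both rules
    he_collective[sizes == 2] = True

    counts = np.zeros(h.n_nodes, dtype=np.int64)
    np.add.at(counts, he_nodes, 1)
    inc_indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    inc_ids = np.empty(he_nodes.size, dtype=np.int64)
    cursor = inc_indptr[:-1].copy()
    edge_of = np.repeat(np.arange(sizes.size, dtype=np.int64), sizes)
    for node, e in zip(he_nodes, edge_of):
        inc_ids[cursor[node]] = e
        cursor[node] += 1
    return inc_indptr, inc_ids, he_offsets, he_nodes, he_beta, he_healing, he_collective


def _initial_state(n: int, x0, rng: np.random.Generator) -> np.ndarray:
    infected = np.zeros(n, dtype=np.uint8)
    if np.isscalar(x0):
        frac = float(x0)
        if not 0 <= frac <= 1:
            raise ValueError("initial infected fraction must be in [0, 1]")
        m = int(round(frac * n))
        if m:
            infected[rng.choice(n, size=m, replace=False)] = 1
    else:
        idx = np.asarray(x0)
        if idx.dtype == bool:
            infected[:] = idx.astype(np.uint8)
        else:
            infected[idx.astype(np.int64)] = 1
    return infected


@dataclass
class SimTrajectory:
    t: np.ndarray
    U: np.ndarray
    infected: np.ndarray  # final state
    event_count: int
    avg_U: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "U": self.U})


def simulate_sis(
    h: Hypergraph,
    params: EpidemicParams,
    x0,
    t_end: float,
    seed: int,
    record_dt: float | None = None,
    avg_from: float = 0.0,
    _state: np.ndarray | None = None,
) -> SimTrajectory:
    """Simulate the SIS chain on hypergraph ``h`` from initial condition
    ``x0`` (fraction, index array, or boolean mask) until ``t_end``.

    Returns the prevalence trajectory sampled every ``record_dt`` (default
    t_end/400) and the time-averaged prevalence over [avg_from, t_end].
    """
    if h.n_nodes == 0:
        raise ValueError("empty hypergraph")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    if _state is None and x0 is None:
        raise ValueError("an initial condition is required")
    infected = _state if _state is not None else _initial_state(h.n_nodes, x0, rng)
    arrays = _build_arrays(h, params)
    if record_dt is None:
        record_dt = t_end / 400
    rec_t, rec_U, avg_U, n_ev = _gillespie(
        h.n_nodes,
        *arrays,
        infected,
        params.gamma,
        float(t_end),
        float(record_dt),
        float(avg_from),
        int(rng.integers(0, 2**31 - 1)),
    )
    return SimTrajectory(rec_t, rec_U, infected, int(n_ev), float(avg_U))


@dataclass
class SweepResult:
    """Adiabatic up-then-down sweep in beta2 with per-step mean prevalence."""

    beta2_path: np.ndarray
    U_mean: np.ndarray
    direction: np.ndarray  # "up"/"down" per step

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(self.beta2_path.size),
                "direction": self.direction,
                "beta2": self.beta2_path,
                "U_mean": self.U_mean,
            }
        )

    def branch(self, direction: str):
        mask = self.direction == direction
        return self.beta2_path[mask], self.U_mean[mask]

    def max_branch_gap(self) -> float:
        """Max over beta2 of (down-branch U - up-branch U), clipped at 0."""
        b2_up, u_up = self.branch("up")
        b2_dn, u_dn = self.branch("down")
        u_dn_matched = u_dn[::-1]  # down path revisits the up path's beta2 values
        return float(np.clip(u_dn_matched - u_up, 0.0, None).max())


def hysteresis_sweep(
    h: Hypergraph,
    params: EpidemicParams,
    beta2_min: float,
    beta2_max: float,
    n_steps: int = 40,
    t_per_step: float | None = None,
    t_transient: float | None = None,
    seed: int = 0,
    x0: float = 0.005,
    record_dt: float | None = None,
) -> SweepResult:
    """Slowly ramp beta2 up from ``beta2_min`` to ``beta2_max`` in
    ``n_steps`` steps and back down, carrying the end state of each step
    into the next.  Per step, prevalence is averaged after discarding a
    transient (defaults: transient 10/gamma, averaging window 30/gamma).

    If the chain goes extinct on the up branch it is re-seeded with the
    initial infected fraction (logged), mirroring the escape from the
    absorbing state needed to trace the upper branch.
    """
    if n_steps < 2:
        raise ValueError("need at least 2 sweep steps")
    g = params.gamma
    if t_transient is None:
        t_transient = 10.0 / g
    if t_per_step is None:
        t_per_step = 30.0 / g
    up = np.linspace(beta2_min, beta2_max, n_steps)
    path = np.concatenate([up, up[::-1]])
    direction = np.array(["up"] * n_steps + ["down"] * n_steps)
    rng = np.random.default_rng(seed)
    infected = _initial_state(h.n_nodes, x0, rng)
    U_mean = np.empty(path.size)
    t_step = t_transient + t_per_step
    for i, b2 in enumerate(path):
        if direction[i] == "up" and infected.sum() == 0:
            log.warning("extinction at sweep step %d (beta2=%g); re-seeding", i, b2)
            infected = _initial_state(h.n_nodes, x0, rng)
        step_params = params.with_(beta2=float(b2))
        traj = simulate_sis(
            h,
            step_params,
            None,
            t_step,
            int(rng.integers(0, 2**31 - 1)),
            record_dt=record_dt,
            avg_from=t_transient,
            _state=infected,
        )
        infected = traj.infected
        U_mean[i] = traj.avg_U
    return SweepResult(path, U_mean, direction)


def bistability_index_sim(
    h_factory,
    params: EpidemicParams,
    beta3_grid,
    beta2_min: float,
    beta2_max: float,
    seeds=(0,),
    n_steps: int = 40,
    t_per_step: float | None = None,
    t_transient: float | None = None,
    x0: float = 0.005,
):
    """Bistability index from microscopic sweeps.

    ``h_factory`` is a Hypergraph or a callable seed -> Hypergraph.  For each
    beta3, B is the maximum up/down branch separation of a hysteresis sweep,
    averaged over seeds.  Returns (beta3_grid, B) arrays; near onset the
    curve is noisy at finite N.
    """
    beta3_grid = np.asarray(beta3_grid, dtype=float)
    B = np.zeros(beta3_grid.size)
    for i, b3 in enumerate(beta3_grid):
        gaps = []
        for s in seeds:
            h = h_factory(s) if callable(h_factory) else h_factory
            sweep = hysteresis_sweep(
                h,
                params.with_(beta3=float(b3)),
                beta2_min,
                beta2_max,
                n_steps=n_steps,
                t_per_step=t_per_step,
                t_transient=t_transient,
                seed=int(s),
                x0=x0,
            )
            gaps.append(sweep.max_branch_gap())
        B[i] = float(np.mean(gaps))
    return beta3_grid, B
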