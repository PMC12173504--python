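"""Compiled (numba) engine for long quasi-stationary runs.

Implements exactly the same stochastic update rule as the pure-Python path in
:mod:`hypercoop.dynamics` / :mod:`hypercoop.quasistationary` — focal draw,
model draw over the co-player union, target-slot draw, source-order draw,
Fermi acceptance — but over packed integer arrays and with numpy's legacy
global RNG inside the jitted code (seeded per run, single-threaded, hence
reproducible).  The reservoir holds equally weighted snapshots recorded at a
fixed cadence, with time-proportional replacement past capacity, so teleport
sampling is uniform over stored snapshots.

Statistical equivalence with the pure-Python engine is asserted in the test
suite via an exact Markov-chain oracle on a small system.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .dynamics import DynamicsConfig, StrategyState
from .games import PayoffScheme
from .structure import Hypergraph

TRIGGER_EITHER = 0
TRIGGER_JOINT = 1


@njit(cache=True, inline="always")
def _total_payoff(i, s_pair, s_tri, pair_nbrs, pair_deg, node_tris, node_ktri,
                  triangles, pay_pair, pay_tri):
    pi = 0.0
    for j in range(pair_deg[i]):
        pi += pay_pair[s_pair[i], s_pair[pair_nbrs[i, j]]]
    for t in range(node_ktri[i]):
        ti = node_tris[i, t]
        nc = 0
        for v in range(3):
            u = triangles[ti, v]
            if u != i and s_tri[u] == 1:
                nc += 1
        pi += pay_tri[s_tri[i], nc]
    return pi


@njit(cache=True, inline="always")
def _fermi(pi_m, pi_f, w):
    x = w * (pi_m - pi_f)
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _is_absorbing(nc_pair, nc_tri, n, scalar, trigger, pswitch):
    if scalar:
        return nc_pair == 0 or nc_pair == n
    if trigger == TRIGGER_EITHER:
        return nc_pair == 0 or nc_pair == n or nc_tri == 0 or nc_tri == n
    if pswitch > 0.0:
        total = nc_pair + nc_tri
        return total == 0 or total == 2 * n
    return (nc_pair == 0 or nc_pair == n) and (nc_tri == 0 or nc_tri == n)


@njit(cache=True)
def _qs_kernel(s_pair, s_tri, pair_nbrs, pair_deg, node_tris, node_ktri,
               triangles, union, union_len, pay_pair, pay_tri,
               w, pswitch, n_mcs, capacity, cadence, trigger, scalar, seed):
    np.random.seed(seed)
    n = s_pair.shape[0]
    densities = np.empty((n_mcs, 2))
    nc_pair = int(s_pair.sum())
    nc_tri = int(s_tri.sum())

    res_pair = np.empty((capacity, n), dtype=np.int8)
    res_tri = np.empty((capacity, n), dtype=np.int8)
    res_count = 0
    total_records = 0

    # seed the reservoir with the (active) initial state
    res_pair[0] = s_pair
    res_tri[0] = s_tri
    res_count = 1
    total_records = 1

    n_teleports = 0
    updates_per_mcs = n if scalar else 2 * n

    for step in range(n_mcs):
        for _ in range(updates_per_mcs):
            f = np.random.randint(0, n)
            m = union[f, np.random.randint(0, union_len[f])]
            pi_f = _total_payoff(f, s_pair, s_tri, pair_nbrs, pair_deg,
                                 node_tris, node_ktri, triangles, pay_pair, pay_tri)
            pi_m = _total_payoff(m, s_pair, s_tri, pair_nbrs, pair_deg,
                                 node_tris, node_ktri, triangles, pay_pair, pay_tri)
            prob = _fermi(pi_m, pi_f, w)
            if scalar:
                if np.random.random() < prob:
                    old = s_pair[f]
                    new = s_pair[m]
                    if new != old:
                        s_pair[f] = new
                        s_tri[f] = new
                        d = 1 if new == 1 else -1
                        nc_pair += d
                        nc_tri += d
            else:
                target_pair = np.random.random() < 0.5
                cross = np.random.random() < pswitch
                if np.random.random() < prob:
                    if target_pair:
                        new = s_tri[m] if cross else s_pair[m]
                        if new != s_pair[f]:
                            nc_pair += 1 if new == 1 else -1
                            s_pair[f] = new
                    else:
                        new = s_pair[m] if cross else s_tri[m]
                        if new != s_tri[f]:
                            nc_tri += 1 if new == 1 else -1
                            s_tri[f] = new
        if _is_absorbing(nc_pair, nc_tri, n, scalar, trigger, pswitch):
            idx = np.random.randint(0, res_count)
            s_pair[:] = res_pair[idx]
            s_tri[:] = res_tri[idx]
            nc_pair = int(s_pair.sum())
            nc_tri = int(s_tri.sum())
            n_teleports += 1
        if (step + 1) % cadence == 0:
            total_records += 1
            if res_count < capacity:
                res_pair[res_count] = s_pair
                res_tri[res_count] = s_tri
                res_count += 1
            else:
                # constant-rate replacement: the stored list tracks the recent
                # active past with an exponentially decaying memory
                idx = np.random.randint(0, capacity)
                res_pair[idx] = s_pair
                res_tri[idx] = s_tri
        densities[step, 0] = nc_pair / n
        densities[step, 1] = nc_tri / n
    return densities, n_teleports


@njit(cache=True)
def _fixation_kernel(s_pair, s_tri, pair_nbrs, pair_deg, node_tris, node_ktri,
                     triangles, union, union_len, pay_pair, pay_tri,
                     w, pswitch, max_updates, scalar, seed):
    np.random.seed(seed)
    n = s_pair.shape[0]
    nc_pair = int(s_pair.sum())
    nc_tri = int(s_tri.sum())
    for u in range(max_updates):
        if _is_absorbing(nc_pair, nc_tri, n, scalar, TRIGGER_JOINT, pswitch):
            return nc_pair + nc_tri, u
        f = np.random.randint(0, n)
        m = union[f, np.random.randint(0, union_len[f])]
        pi_f = _total_payoff(f, s_pair, s_tri, pair_nbrs, pair_deg,
                             node_tris, node_ktri, triangles, pay_pair, pay_tri)
        pi_m = _total_payoff(m, s_pair, s_tri, pair_nbrs, pair_deg,
                             node_tris, node_ktri, triangles, pay_pair, pay_tri)
        prob = _fermi(pi_m, pi_f, w)
        if scalar:
            if np.random.random() < prob:
                old = s_pair[f]
                new = s_pair[m]
                if new != old:
                    s_pair[f] = new
                    s_tri[f] = new
                    d = 1 if new == 1 else -1
                    nc_pair += d
                    nc_tri += d
        else:
            target_pair = np.random.random() < 0.5
            cross = np.random.random() < pswitch
            if np.random.random() < prob:
                if target_pair:
                    new = s_tri[m] if cross else s_pair[m]
                    if new != s_pair[f]:
                        nc_pair += 1 if new == 1 else -1
                        s_pair[f] = new
                else:
                    new = s_pair[m] if cross else s_tri[m]
                    if new != s_tri[f]:
                        nc_tri += 1 if new == 1 else -1
                        s_tri[f] = new
    return -1, max_updates


def _pack(h: Hypergraph, scheme: PayoffScheme):
    arrs = h.to_arrays()
    return (
        arrs["pair_nbrs"], arrs["pair_deg"], arrs["node_tris"], arrs["node_ktri"],
        arrs["triangles"], arrs["union"], arrs["union_len"],
        scheme.pair_matrix(), scheme.tri_table(),
    )


def _slots(state: StrategyState) -> tuple[np.ndarray, np.ndarray, bool]:
    if state.mode == "scalar":
        s = state.slot.copy()
        return s, s.copy(), True
    return state.pair.copy(), state.tri.copy(), False


def evolve_qs_compiled(
    h: Hypergraph,
    state: StrategyState,
    scheme: PayoffScheme,
    cfg: DynamicsConfig,
    n_mcs: int,
    reservoir_cfg,
    rng: np.random.Generator,
):
    """Compiled counterpart of the pure-Python quasi-stationary evolution."""
    from .quasistationary import QSTrajectory

    if cfg.neighbour_rule != "union_unique":
        raise ValueError("compiled engine supports the union_unique neighbour rule only")
    pair_nbrs, pair_deg, node_tris, node_ktri, triangles, union, union_len, pp, pt = _pack(
        h, scheme
    )
    s_pair, s_tri, scalar = _slots(state)
    trigger = TRIGGER_EITHER if cfg.absorbing_trigger == "either_layer" else TRIGGER_JOINT
    seed = int(rng.integers(2**31))
    dens2, n_teleports = _qs_kernel(
        s_pair, s_tri, pair_nbrs, pair_deg, node_tris, node_ktri, triangles,
        union, union_len, pp, pt,
        float(cfg.w), float(cfg.pswitch), int(n_mcs),
        int(reservoir_cfg.capacity), int(reservoir_cfg.cadence),
        trigger, scalar, seed,
    )
    densities = np.column_stack([dens2, dens2.mean(axis=1)])
    if scalar:
        final = StrategyState("scalar", slot=s_pair)
    else:
        final = StrategyState("vector", pair=s_pair, tri=s_tri)
    return QSTrajectory(densities, int(n_teleports), final)


def run_to_fixation_compiled(
    h: Hypergraph,
    state: StrategyState,
    scheme: PayoffScheme,
    cfg: DynamicsConfig,
    max_updates: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Plain (no teleports) evolution until the joint absorbing trigger fires.

    Returns ``(total cooperator slots at absorption, updates used)``; the first
    element is ``-1`` if the run did not absorb within ``max_updates``.  For
    ``pswitch > 0`` vector dynamics the absorbing values are 0 (all-defect) and
    2N (all-cooperate); scalar runs report 2N on all-cooperate as both slot
    views coincide.
    """
    pair_nbrs, pair_deg, node_tris, node_ktri, triangles, union, union_len, pp, pt = _pack(
        h, scheme
    )
    s_pair, s_tri, scalar = _slots(state)
    seed = int(rng.integers(2**31))
    result, used = _fixation_kernel(
        s_pair, s_tri, pair_nbrs, pair_deg, node_tris, node_ktri, triangles,
        union, union_len, pp, pt,
        float(cfg.w), float(cfg.pswitch), int(max_updates), scalar, seed,
    )
    return int(result), int(used)
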