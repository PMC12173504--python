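"""Run orchestration: single runs, ensembles, parameter sweeps, exact oracles.

A *run* builds a fresh random-regular hypergraph at the requested overlap,
initialises exact-count cooperator densities in both strategy slots, evolves
the system quasi-stationarily, and time-averages the cooperation densities
over the final stationary window.  An *ensemble* repeats this over M
independent runs (fresh structure and dynamics per run) with seeds spawned
from a master seed, and reports ensemble means with standard errors.

For systems with at most 12 strategy slots, :func:`exact_small_system_oracle`
builds the exact one-step transition matrix of the elementary-update chain and
solves absorption probabilities by linear algebra — the independent check the
stochastic engines are validated against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure import Hypergraph, build_full_overlap, compute_overlap, co_players, rewire_to_overlap
from .games import PayoffScheme, make_scheme, total_payoff
from .dynamics import (
    DynamicsConfig,
    StrategyState,
    fermi_probability,
    is_absorbing,
    outcome_probabilities,
)
from .quasistationary import ReservoirConfig, evolve_quasistationary

__all__ = [
    "ExperimentConfig",
    "EnsembleResult",
    "initialize_state",
    "run_single",
    "run_ensemble",
    "sweep",
    "exact_small_system_oracle",
    "OracleResult",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one ensemble point.

    Defaults are the full study scale (N=1500, k_pair=4, k_tri=2, 10^5 MCS with
    the last 10^4 as the stationary window, M=400 runs, half-and-half initial
    strategies).  :meth:`scaled_down` gives the desk-scale variant used
    throughout the test suite.  ``w=None`` resolves to ``1/(k_pair + k_tri)``.
    """

    n_nodes: int = 1500
    k_pair: int = 4
    k_tri: int = 2
    omega_target: float = 1.0
    alpha: float = -0.5
    pswitch: float = 0.0
    w: float | None = None
    rho0_pair: float = 0.5
    rho0_tri: float = 0.5
    n_mcs: int = 100_000
    stationary_window: int = 10_000
    n_runs: int = 400
    mode: str = "vector"
    master_seed: int = 0
    omega_tol: float = 0.01
    neighbour_rule: str = "union_unique"
    absorbing_trigger: str = "either_layer"
    reservoir_capacity: int = 20
    reservoir_cadence: int = 1
    engine: str = "auto"

    def __post_init__(self) -> None:
        for name in ("rho0_pair", "rho0_tri"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.stationary_window > self.n_mcs:
            raise ValueError("stationary_window cannot exceed n_mcs")
        if not (0.0 <= self.omega_target <= 1.0):
            raise ValueError("omega_target must be in [0, 1]")

    @property
    def noise(self) -> float:
        """Effective Fermi noise: explicit ``w`` or ``1/(k_pair + k_tri)``."""
        return self.w if self.w is not None else 1.0 / (self.k_pair + self.k_tri)

    def scheme(self) -> PayoffScheme:
        return make_scheme(self.alpha)

    def dynamics_config(self) -> DynamicsConfig:
        return DynamicsConfig(
            w=self.noise,
            pswitch=self.pswitch,
            mode=self.mode,
            neighbour_rule=self.neighbour_rule,
            absorbing_trigger=self.absorbing_trigger,
        )

    @classmethod
    def scaled_down(cls, **overrides) -> "ExperimentConfig":
        """Desk-scale point: N=300, 2x10^4 MCS, window 2x10^3, M=20 runs."""
        base = dict(n_nodes=300, n_mcs=20_000, stationary_window=2_000, n_runs=20)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__  # noqa: SLF001 - dataclass introspection
        }
        d["w"] = self.noise
        d["payoffs"] = self.scheme().as_dict()
        return d


@dataclass(frozen=True)
class EnsembleResult:
    """Per-run stationary densities plus their ensemble aggregates."""

    per_run: np.ndarray  # (n_runs, 3): rho_pair, rho_tri, rho
    config: ExperimentConfig

    @property
    def mean_rho_pair(self) -> float:
        return float(self.per_run[:, 0].mean())

    @property
    def mean_rho_tri(self) -> float:
        return float(self.per_run[:, 1].mean())

    @property
    def mean_rho(self) -> float:
        return float(self.per_run[:, 2].mean())

    @property
    def se_rho(self) -> float:
        m = len(self.per_run)
        if m == 1:
            return 0.0
        return float(self.per_run[:, 2].std(ddof=1) / np.sqrt(m))


def initialize_state(
    n_nodes: int,
    rho0_pair: float,
    rho0_tri: float,
    mode: str,
    rng: np.random.Generator,
) -> StrategyState:
    """Exact-count random initial strategies.

    Exactly ``round(rho0 * N)`` cooperators per slot type, placed uniformly at
    random without replacement and independently per slot.  Scalar mode uses
    ``rho0_pair`` for its single slot.
    """

    def slot(rho0: float) -> np.ndarray:
        arr = np.zeros(n_nodes, dtype=np.int8)
        n_c = int(round(rho0 * n_nodes))
        arr[rng.choice(n_nodes, size=n_c, replace=False)] = 1
        return arr

    if mode == "vector":
        return StrategyState("vector", pair=slot(rho0_pair), tri=slot(rho0_tri))
    return StrategyState("scalar", slot=slot(rho0_pair))


def build_structure(cfg: ExperimentConfig, rng: np.random.Generator) -> Hypergraph:
    """Fresh full-overlap hypergraph, rewired down to the configured overlap."""
    h = build_full_overlap(cfg.n_nodes, cfg.k_pair, cfg.k_tri, seed=rng)
    if compute_overlap(h).omega - cfg.omega_target > cfg.omega_tol:
        h = rewire_to_overlap(
            h, cfg.omega_target, tolerance=cfg.omega_tol, seed=rng
        )
    return h


def run_single(cfg: ExperimentConfig, run_seed) -> tuple[float, float, float]:
    """One independent run; returns stationary (rho_pair, rho_tri, rho).

    The hypergraph is regenerated and rewired with the run seed, so ensemble
    averages integrate over structural as well as dynamical randomness.
    """
    rng = np.random.default_rng(run_seed)
    h = build_structure(cfg, rng)
    state = initialize_state(cfg.n_nodes, cfg.rho0_pair, cfg.rho0_tri, cfg.mode, rng)
    traj = evolve_quasistationary(
        h,
        state,
        cfg.scheme(),
        cfg.dynamics_config(),
        cfg.n_mcs,
        reservoir_cfg=ReservoirConfig(cfg.reservoir_capacity, cfg.reservoir_cadence),
        rng=rng,
        engine=cfg.engine,
    )
    window = traj.densities[-cfg.stationary_window :]
    means = window.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def _run_seeds(master_seed: int, n_runs: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n_runs)


def run_ensemble(cfg: ExperimentConfig, progress: bool = False) -> EnsembleResult:
    """M independent runs with per-run seeds spawned from the master seed."""
    if cfg.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    per_run = np.empty((cfg.n_runs, 3))
    for i, seed in enumerate(_run_seeds(cfg.master_seed, cfg.n_runs)):
        per_run[i] = run_single(cfg, seed)
        if progress:
            print(f"  run {i + 1}/{cfg.n_runs}: rho={per_run[i, 2]:.3f}", flush=True)
    return EnsembleResult(per_run=per_run, config=cfg)


def sweep(
    base_cfg: ExperimentConfig,
    pswitch_values=None,
    omega_values=None,
    alpha_values=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Cartesian-product ensemble sweep; one long-format row per grid point.

    Every grid point reuses the base master seed, so grid points that do not
    actually consume a parameter (e.g. ``pswitch`` in scalar mode) reproduce
    identical results, and the whole table is reproducible byte-for-byte.
    """
    pswitch_values = list(pswitch_values) if pswitch_values is not None else [base_cfg.pswitch]
    omega_values = list(omega_values) if omega_values is not None else [base_cfg.omega_target]
    alpha_values = list(alpha_values) if alpha_values is not None else [base_cfg.alpha]
    if not (pswitch_values and omega_values and alpha_values):
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for ps, om, al in itertools.product(pswitch_values, omega_values, alpha_values):
        cfg = replace(base_cfg, pswitch=ps, omega_target=om, alpha=al)
        if progress:
            print(f"point pswitch={ps} omega={om} alpha={al}", flush=True)
        res = run_ensemble(cfg, progress=progress)
        row = {
            "n_nodes": cfg.n_nodes,
            "k_pair": cfg.k_pair,
            "k_tri": cfg.k_tri,
            "omega_target": om,
            "alpha": al,
            "pswitch": ps,
            "w": cfg.noise,
            "mode": cfg.mode,
            "n_mcs": cfg.n_mcs,
            "stationary_window": cfg.stationary_window,
            "n_runs": cfg.n_runs,
            "master_seed": cfg.master_seed,
            "rho_pair_mean": res.mean_rho_pair,
            "rho_tri_mean": res.mean_rho_tri,
            "rho_mean": res.mean_rho,
            "rho_se": res.se_rho,
        }
        rows.append(row)
    return pd.DataFrame(rows)


# -- exact small-system oracle ----------------------------------------------


@dataclass
class OracleResult:
    """Exact chain of a small system: transition matrix and absorption solve."""

    n_nodes: int
    mode: str
    transition_matrix: np.ndarray  # (S, S), row-stochastic
    absorbing_states: tuple[int, ...]
    _absorption: dict[int, dict[int, float]] = field(repr=False, default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def encode(self, state: StrategyState) -> int:
        bits = (
            np.concatenate([state.pair, state.tri])
            if self.mode == "vector"
            else state.slot
        )
        return int(sum(int(b) << i for i, b in enumerate(bits)))

    def decode(self, code: int) -> StrategyState:
        n_slots = 2 * self.n_nodes if self.mode == "vector" else self.n_nodes
        bits = np.array([(code >> i) & 1 for i in range(n_slots)], dtype=np.int8)
        if self.mode == "vector":
            return StrategyState("vector", pair=bits[: self.n_nodes], tri=bits[self.n_nodes :])
        return StrategyState("scalar", slot=bits)

    @property
    def all_defect_state(self) -> int:
        return 0

    @property
    def all_cooperate_state(self) -> int:
        n_slots = 2 * self.n_nodes if self.mode == "vector" else self.n_nodes
        return (1 << n_slots) - 1

    def absorption_probabilities(self, initial: int | StrategyState) -> dict[int, float]:
        """Probability of ending in each absorbing state from ``initial``."""
        code = initial if isinstance(initial, int) else self.encode(initial)
        if code in self._absorption:
            return self._absorption[code]
        if code in self.absorbing_states:
            return {a: float(a == code) for a in self.absorbing_states}
        P = self.transition_matrix
        transient = [s for s in range(self.n_states) if s not in self.absorbing_states]
        t_index = {s: i for i, s in enumerate(transient)}
        Q = P[np.ix_(transient, transient)]
        R = P[np.ix_(transient, list(self.absorbing_states))]
        B = np.linalg.solve(np.eye(len(transient)) - Q, R)
        for s in transient:
            self._absorption[s] = {
                a: float(B[t_index[s], j]) for j, a in enumerate(self.absorbing_states)
            }
        return self._absorption[code]

    def quasi_stationary_distribution(self) -> dict[int, float]:
        """Left principal eigenvector of the transient block, normalised."""
        transient = [s for s in range(self.n_states) if s not in self.absorbing_states]
        Q = self.transition_matrix[np.ix_(transient, transient)]
        vals, vecs = np.linalg.eig(Q.T)
        k = int(np.argmax(vals.real))
        v = np.abs(vecs[:, k].real)
        v = v / v.sum()
        return {s: float(v[i]) for i, s in enumerate(transient)}


def exact_small_system_oracle(
    h_small: Hypergraph,
    scheme: PayoffScheme,
    cfg: DynamicsConfig,
) -> OracleResult:
    """Exact one-step transition matrix of the elementary-update chain.

    Enumerates every joint strategy configuration (at most 2^12 of them),
    composes the focal/model/slot/source/acceptance probabilities analytically,
    and marks the states no update can leave as absorbing.  Intended as the
    independent oracle for the stochastic engines on toy systems.
    """
    n = h_small.n_nodes
    n_slots = 2 * n if cfg.mode == "vector" else n
    if n_slots > 12:
        raise ValueError(f"state space too large: {n_slots} slots > 12")
    n_states = 1 << n_slots

    unions = []
    for i in range(n):
        _, _, u = co_players(h_small, i)
        if cfg.neighbour_rule == "union_unique":
            unions.append(sorted(u))
        else:
            raise ValueError("oracle implements the union_unique neighbour rule")
        if not u:
            raise ValueError(f"node {i} has no co-players")

    result = OracleResult(n, cfg.mode, np.zeros((n_states, n_states)), ())
    P = result.transition_matrix
    for code in range(n_states):
        state = result.decode(code)
        for f in range(n):
            p_focal = 1.0 / n
            for m in unions[f]:
                p_fm = p_focal / len(unions[f])
                pi_f = total_payoff(h_small, state, f, scheme)
                pi_m = total_payoff(h_small, state, m, scheme)
                prob = fermi_probability(pi_m, pi_f, cfg.w)
                if cfg.mode == "vector":
                    probs = outcome_probabilities(prob, cfg.pswitch)
                    moves = {
                        "pair<-pair": (f, int(state.pair[m])),
                        "pair<-tri": (f, int(state.tri[m])),
                        "tri<-tri": (n + f, int(state.tri[m])),
                        "tri<-pair": (n + f, int(state.pair[m])),
                    }
                    for key, (bit, value) in moves.items():
                        new = (code & ~(1 << bit)) | (value << bit)
                        P[code, new] += p_fm * probs[key]
                    P[code, code] += p_fm * probs["no_change"]
                else:
                    value = int(state.slot[m])
                    new = (code & ~(1 << f)) | (value << f)
                    P[code, new] += p_fm * prob
                    P[code, code] += p_fm * (1.0 - prob)
    absorbing = tuple(
        s for s in range(n_states) if abs(P[s, s] - 1.0) < 1e-12
    )
    result.absorbing_states = absorbing
    return result
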