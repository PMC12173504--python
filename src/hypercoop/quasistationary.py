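"""Quasi-stationary evolution: teleport out of absorbing states.

Imitation dynamics with finite populations eventually freezes in homogeneous
(absorbing) configurations, so long-run averages of the raw chain say nothing
about the active phase.  The quasi-stationary method conditions on survival:
whenever the chain absorbs, it is teleported back to a previously visited
active configuration, sampled with probability proportional to the time the
chain spent there.  A bounded reservoir of state snapshots with an
exponentially decaying (recent-past) memory realises that sampling law with
constant storage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Hypergraph
from .games import PayoffScheme
from .dynamics import DynamicsConfig, StrategyState, is_absorbing, monte_carlo_step

__all__ = ["QSReservoir", "ReservoirConfig", "QSTrajectory", "evolve_quasistationary"]


@dataclass(frozen=True)
class ReservoirConfig:
    """Snapshot store bounds: at most ``capacity`` states, recorded every
    ``cadence`` MCS.

    The store is a sliding window over the recent active past (constant-rate
    replacement), so ``capacity * cadence`` sets its memory depth in MCS.  A
    short memory is essential: teleport targets must follow the current
    survival-conditioned distribution, and a long memory re-injects stale
    transient states, biasing the stationary densities away from the absorbing
    boundaries the chain hovers at.
    """

    capacity: int = 20
    cadence: int = 1


class QSReservoir:
    """Bounded store of active-state snapshots with dwell-time weights.

    While below capacity every recorded state is kept; past capacity each new
    record overwrites a uniformly chosen stored snapshot, so the store tracks
    the recently visited active states with an exponentially decaying memory —
    the standard bookkeeping for quasi-stationary simulation.  Teleporting
    samples a stored snapshot with probability ``weight / total_weight``,
    i.e. proportionally to the dwell time it represents.
    """

    def __init__(
        self,
        capacity: int,
        cfg: DynamicsConfig,
        rng: np.random.Generator | None = None,
    ):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng()
        self.snapshots: list[tuple[StrategyState, float]] = []
        self.total_records = 0

    @property
    def total_weight(self) -> float:
        return sum(w for _, w in self.snapshots)

    def record(self, state: StrategyState, dwell: float) -> "QSReservoir":
        if dwell <= 0:
            raise ValueError("dwell weight must be positive")
        if is_absorbing(state, self.cfg):
            raise ValueError("refusing to record an absorbing state")
        self.total_records += 1
        snap = (state.copy(), dwell)
        if len(self.snapshots) < self.capacity:
            self.snapshots.append(snap)
        else:
            # constant-rate replacement: a uniformly chosen stored snapshot is
            # overwritten, so the store follows the recent active past with an
            # exponentially decaying memory (the standard quasi-stationary
            # simulation scheme)
            idx = int(self.rng.integers(self.capacity))
            self.snapshots[idx] = snap
        return self

    def teleport(self, rng: np.random.Generator) -> StrategyState:
        """A copy of a stored snapshot, sampled proportionally to dwell weight."""
        if not self.snapshots:
            raise RuntimeError(
                "empty reservoir: absorption before any active state was recorded"
            )
        weights = np.array([w for _, w in self.snapshots])
        idx = int(rng.choice(len(self.snapshots), p=weights / weights.sum()))
        return self.snapshots[idx][0].copy()


@dataclass
class QSTrajectory:
    """Per-MCS density trajectory of a quasi-stationary run."""

    densities: np.ndarray  # (n_mcs, 3): rho_pair, rho_tri, rho
    n_teleports: int
    final_state: StrategyState

    @property
    def rho_pair(self) -> np.ndarray:
        return self.densities[:, 0]

    @property
    def rho_tri(self) -> np.ndarray:
        return self.densities[:, 1]

    @property
    def rho(self) -> np.ndarray:
        return self.densities[:, 2]


def evolve_quasistationary(
    h: Hypergraph,
    state: StrategyState,
    scheme: PayoffScheme,
    cfg: DynamicsConfig,
    n_mcs: int,
    reservoir_cfg: ReservoirConfig | None = None,
    rng: np.random.Generator | None = None,
    engine: str = "auto",
) -> QSTrajectory:
    """Run ``n_mcs`` Monte Carlo steps under the quasi-stationary rule.

    After every MCS the state is checked against the absorbing trigger; on
    absorption it is replaced by a reservoir teleport before the run continues.
    Active states are recorded into the reservoir at the configured cadence,
    starting with the (active) initial state so a teleport target always
    exists.  The input state is not mutated.

    ``engine="numba"`` uses the compiled kernel (same stochastic rule, its own
    RNG stream seeded from ``rng``); ``"python"`` the pure-Python update path;
    ``"auto"`` picks the kernel whenever the configuration supports it
    (union-unique neighbour rule).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if reservoir_cfg is None:
        reservoir_cfg = ReservoirConfig()
    if is_absorbing(state, cfg):
        raise ValueError("initial state is absorbing")
    if engine == "auto":
        engine = "numba" if cfg.neighbour_rule == "union_unique" else "python"
    if engine == "numba":
        from . import _engine

        return _engine.evolve_qs_compiled(h, state, scheme, cfg, n_mcs, reservoir_cfg, rng)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    work = state.copy()
    reservoir = QSReservoir(reservoir_cfg.capacity, cfg, rng)
    reservoir.record(work, reservoir_cfg.cadence)
    densities = np.empty((n_mcs, 3))
    n_teleports = 0
    for t in range(n_mcs):
        monte_carlo_step(h, work, scheme, cfg, rng)
        if is_absorbing(work, cfg):
            work = reservoir.teleport(rng)
            n_teleports += 1
        if (t + 1) % reservoir_cfg.cadence == 0:
            reservoir.record(work, reservoir_cfg.cadence)
        densities[t] = (work.rho_pair, work.rho_tri, work.rho)
    return QSTrajectory(densities, n_teleports, work)
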