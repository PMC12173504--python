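"""Fermi imitation dynamics with inter-order strategy coupling.

Each node carries a two-slot strategy vector: one strategy for pairwise games
and one for triangle games (or a single scalar slot in baseline mode).  An
elementary update picks a random focal player and one of its co-players as the
model, computes both players' total payoffs over *all* their games in both
layers, and lets the focal player imitate one of the model's slots with the
Fermi probability

    Pi_t = 1 / (1 + exp(-w (pi_m - pi_f))),

where ``w`` is the selection noise.  Which focal slot is updated is uniform
(the 1/2 factor), and with probability ``pswitch`` the copied strategy comes
from the model's *other* interaction order — the dynamical coupling between
orders.  One Monte Carlo step (MCS) is 2N elementary updates in vector mode
(each slot updated once on average) and N updates in scalar mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Hypergraph, co_players
from .games import PayoffScheme, total_payoff

__all__ = [
    "StrategyState",
    "DynamicsConfig",
    "UpdateEvent",
    "fermi_probability",
    "outcome_probabilities",
    "pick_focal_and_model",
    "elementary_update",
    "scalar_update",
    "monte_carlo_step",
    "is_absorbing",
]


@dataclass
class StrategyState:
    """Per-node strategies, encoded 1 = cooperate, 0 = defect (int8 arrays).

    ``mode="vector"``: independent ``pair`` and ``tri`` slots per node.
    ``mode="scalar"``: one ``slot`` array used at both interaction orders.
    """

    mode: str
    pair: np.ndarray | None = None
    tri: np.ndarray | None = None
    slot: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode == "vector":
            if self.pair is None or self.tri is None:
                raise ValueError("vector mode needs pair and tri slot arrays")
            self.pair = np.asarray(self.pair, dtype=np.int8)
            self.tri = np.asarray(self.tri, dtype=np.int8)
            if self.pair.shape != self.tri.shape:
                raise ValueError("slot arrays must have equal length")
        elif self.mode == "scalar":
            if self.slot is None:
                raise ValueError("scalar mode needs a slot array")
            self.slot = np.asarray(self.slot, dtype=np.int8)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.pair_strategy)

    @property
    def pair_strategy(self) -> np.ndarray:
        """Strategies used in pairwise games (the scalar slot in scalar mode)."""
        return self.pair if self.mode == "vector" else self.slot

    @property
    def tri_strategy(self) -> np.ndarray:
        """Strategies used in triangle games (the scalar slot in scalar mode)."""
        return self.tri if self.mode == "vector" else self.slot

    @property
    def rho_pair(self) -> float:
        return float(self.pair_strategy.mean())

    @property
    def rho_tri(self) -> float:
        return float(self.tri_strategy.mean())

    @property
    def rho(self) -> float:
        """Overall cooperation density: mean of the two layer densities."""
        return 0.5 * (self.rho_pair + self.rho_tri)

    def copy(self) -> "StrategyState":
        if self.mode == "vector":
            return StrategyState("vector", pair=self.pair.copy(), tri=self.tri.copy())
        return StrategyState("scalar", slot=self.slot.copy())


@dataclass
class DynamicsConfig:
    """Knobs of the update rule.

    ``w``: Fermi noise (inverse payoff scale); ``w -> 0`` makes copying a coin
    flip, ``w -> inf`` deterministic payoff ranking.  ``pswitch``: probability
    that an accepted imitation copies the model's strategy from the other
    interaction order.  ``neighbour_rule``: how the model player is drawn —
    ``union_unique`` (uniform over the de-duplicated union of co-players across
    both layers, the default) or ``layer_then_neighbour`` (pick a layer with
    probability 1/2, then a uniform co-player within it).
    ``absorbing_trigger``: ``either_layer`` declares the state absorbed as soon
    as one layer is strategy-homogeneous; ``joint`` only when no elementary
    update can change anything.
    """

    w: float
    pswitch: float = 0.0
    mode: str = "vector"
    neighbour_rule: str = "union_unique"
    absorbing_trigger: str = "either_layer"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("noise w must be >= 0")
        if not (0.0 <= self.pswitch <= 1.0):
            raise ValueError("pswitch must be in [0, 1]")
        if self.mode not in ("vector", "scalar"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.neighbour_rule not in ("union_unique", "layer_then_neighbour"):
            raise ValueError(f"unknown neighbour_rule {self.neighbour_rule!r}")
        if self.absorbing_trigger not in ("either_layer", "joint"):
            raise ValueError(f"unknown absorbing_trigger {self.absorbing_trigger!r}")


@dataclass(frozen=True)
class UpdateEvent:
    """Record of one elementary update attempt."""

    focal: int
    model: int
    target_slot: str  # "pair" | "tri" | "scalar"
    source_slot: str
    fermi_prob: float
    accepted: bool


def fermi_probability(payoff_model: float, payoff_focal: float, w: float) -> float:
    """Imitation probability 1/(1+exp(-w*(pi_m - pi_f))), overflow-safe."""
    x = w * (payoff_model - payoff_focal)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def outcome_probabilities(fermi_prob: float, pswitch: float) -> dict[str, float]:
    """Probabilities of the five outcomes of one vector-mode elementary update.

    Four copy events (target slot x source order) plus no change; they sum to
    one for any Fermi probability and coupling.
    """
    p, q = fermi_prob, pswitch
    return {
        "pair<-pair": 0.5 * (1 - q) * p,
        "pair<-tri": 0.5 * q * p,
        "tri<-tri": 0.5 * (1 - q) * p,
        "tri<-pair": 0.5 * q * p,
        "no_change": 1 - p,
    }


def pick_focal_and_model(
    h: Hypergraph,
    rng: np.random.Generator,
    neighbour_rule: str = "union_unique",
) -> tuple[int, int]:
    """Uniform focal player, then a model among its co-players.

    The default rule draws the model uniformly from the de-duplicated union of
    pairwise neighbours and triangle partners; ``layer_then_neighbour`` first
    picks a layer (1/2 each, among non-empty ones) and then a uniform co-player
    within it.
    """
    focal = int(rng.integers(h.n_nodes))
    pair, tri, union = co_players(h, focal)
    if not union:
        raise ValueError(f"node {focal} has no co-players")
    if neighbour_rule == "union_unique":
        pool = sorted(union)
    else:
        choices = [sorted(s) for s in (pair, tri) if s]
        pool = choices[int(rng.integers(len(choices)))] if len(choices) > 1 else choices[0]
    model = pool[int(rng.integers(len(pool)))]
    return focal, model


def elementary_update(
    h: Hypergraph,
    state: StrategyState,
    scheme: PayoffScheme,
    cfg: DynamicsConfig,
    rng: np.random.Generator,
) -> UpdateEvent:
    """One vector-mode update; mutates ``state`` in place.

    Draw order is fixed for reproducibility: focal, model, target slot, source
    order, acceptance.  Both players' payoffs are recomputed from scratch over
    all their games in both layers.  At most one focal slot changes.
    """
    if state.mode != "vector":
        raise ValueError("elementary_update requires vector mode")
    focal, model = pick_focal_and_model(h, rng, cfg.neighbour_rule)
    pi_f = total_payoff(h, state, focal, scheme)
    pi_m = total_payoff(h, state, model, scheme)
    prob = fermi_probability(pi_m, pi_f, cfg.w)
    target = "pair" if rng.random() < 0.5 else "tri"
    cross = rng.random() < cfg.pswitch
    source = ("tri" if target == "pair" else "pair") if cross else target
    accepted = rng.random() < prob
    if accepted:
        value = state.pair[model] if source == "pair" else state.tri[model]
        if target == "pair":
            state.pair[focal] = value
        else:
            state.tri[focal] = value
    return UpdateEvent(focal, model, target, source, prob, accepted)


def scalar_update(
    h: Hypergraph,
    state: StrategyState,
    scheme: PayoffScheme,
    cfg: DynamicsConfig,
    rng: np.random.Generator,
) -> UpdateEvent:
    """One scalar-mode update: the focal copies the model's single strategy.

    The scalar slot is used at both interaction orders when accumulating
    payoffs; there is no slot or source distinction (inter-order coupling is
    meaningless with one strategy per node).
    """
    if state.mode != "scalar":
        raise ValueError("scalar_update requires scalar mode")
    focal, model = pick_focal_and_model(h, rng, cfg.neighbour_rule)
    pi_f = total_payoff(h, state, focal, scheme)
    pi_m = total_payoff(h, state, model, scheme)
    prob = fermi_probability(pi_m, pi_f, cfg.w)
    accepted = rng.random() < prob
    if accepted:
        state.slot[focal] = state.slot[model]
    return UpdateEvent(focal, model, "scalar", "scalar", prob, accepted)


def monte_carlo_step(
    h: Hypergraph,
    state: StrategyState,
    scheme: PayoffScheme,
    cfg: DynamicsConfig,
    rng: np.random.Generator,
) -> StrategyState:
    """One MCS: 2N elementary updates (vector) or N (scalar), in place."""
    n = state.n_nodes
    if n != h.n_nodes:
        raise ValueError("state and hypergraph sizes differ")
    if cfg.mode == "vector":
        for _ in range(2 * n):
            elementary_update(h, state, scheme, cfg, rng)
    else:
        for _ in range(n):
            scalar_update(h, state, scheme, cfg, rng)
    return state


def _homogeneous(a: np.ndarray) -> bool:
    s = int(a.sum())
    return s == 0 or s == len(a)


def is_absorbing(state: StrategyState, cfg: DynamicsConfig) -> bool:
    """Whether the dynamics has hit an absorbing configuration.

    ``either_layer`` (default): one layer fully homogeneous — full cooperation
    or full defection in pairwise *or* triangle slots.  ``joint``: no
    elementary update can change the state, i.e. all 2N slot values identical
    when ``pswitch > 0`` (cross-order copies couple the layers), or each layer
    homogeneous on its own when ``pswitch = 0``.  Scalar mode: the single slot
    array homogeneous.
    """
    if state.mode == "scalar":
        return _homogeneous(state.slot)
    if cfg.absorbing_trigger == "either_layer":
        return _homogeneous(state.pair) or _homogeneous(state.tri)
    if cfg.pswitch > 0:
        total = int(state.pair.sum()) + int(state.tri.sum())
        return total == 0 or total == 2 * state.n_nodes
    return _homogeneous(state.pair) and _homogeneous(state.tri)
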