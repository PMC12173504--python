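"""Payoff structures: pairwise prisoner's dilemma plus a three-player payoff cube.

The two-player game is the standard prisoner's dilemma matrix with reward R,
sucker's payoff S, temptation T and punishment P, ordered T > R > P > S.  The
three-player game is a symmetric 2x2x2 payoff cube that reuses the four corner
payoffs (unanimous-partner profiles) and adds two genuinely multi-player
entries:

* ``G_tri`` — payoff of a cooperator whose two partners split (one C, one D);
* ``W_tri`` — payoff of a defector whose two partners split.

The *dilemma strength* ``alpha = W_tri - G_tri`` tunes how harshly cooperation
is punished in mixed groups: ``alpha > 0`` yields a strong social dilemma (all
Nash social-dilemma conditions hold; full defection is the unique equilibrium),
``alpha < 0`` a relaxed one (the mixed profile {C,C,D} is also an equilibrium).

To keep orders comparable — so that one triangle of partners is worth exactly
two pair games against the same partners, with no synergistic group bonus —
the cube corners double the pairwise values: ``X_tri = 2*X_pair`` for X in
{R, S, T, P}.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Strategy",
    "PayoffScheme",
    "DilemmaReport",
    "make_scheme",
    "pair_payoffs",
    "triple_payoffs",
    "classify_dilemma",
    "total_payoff",
]


class Strategy(enum.Enum):
    C = "C"
    D = "D"


C, D = Strategy.C, Strategy.D

#: array encoding used throughout the simulation engine
STRATEGY_TO_INT = {Strategy.C: 1, Strategy.D: 0}
INT_TO_STRATEGY = {1: Strategy.C, 0: Strategy.D}


@dataclass(frozen=True)
class PayoffScheme:
    """All payoff entries of the two games.

    The constructor is total: no ordering is enforced here so that degenerate
    toy games (e.g. all payoffs equal, for neutral-drift oracles) can be built
    directly.  :func:`make_scheme` is the validating entry point for proper
    prisoner's-dilemma schemes.
    """

    R_pair: float
    S_pair: float
    T_pair: float
    P_pair: float
    R_tri: float
    S_tri: float
    T_tri: float
    P_tri: float
    G_tri: float
    W_tri: float

    @property
    def alpha(self) -> float:
        """Dilemma strength of the three-player game, ``W_tri - G_tri``."""
        return self.W_tri - self.G_tri

    def pair_matrix(self) -> np.ndarray:
        """Focal payoff indexed ``[s_focal, s_other]`` with 1 = C, 0 = D."""
        return np.array(
            [[self.P_pair, self.T_pair], [self.S_pair, self.R_pair]], dtype=np.float64
        )

    def tri_table(self) -> np.ndarray:
        """Focal payoff indexed ``[s_focal, n_cooperating_partners]``."""
        return np.array(
            [
                [self.P_tri, self.W_tri, self.T_tri],
                [self.S_tri, self.G_tri, self.R_tri],
            ],
            dtype=np.float64,
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            k: getattr(self, k)
            for k in (
                "R_pair", "S_pair", "T_pair", "P_pair",
                "R_tri", "S_tri", "T_tri", "P_tri", "G_tri", "W_tri",
            )
        }
        d["alpha"] = self.alpha
        return d


def make_scheme(
    alpha: float,
    T_pair: float = 1.1,
    R_pair: float = 1.0,
    P_pair: float = 0.0,
    S_pair: float = -0.1,
    W_tri: float = 0.7,
) -> PayoffScheme:
    """Build the comparability-constrained scheme for a given dilemma strength.

    The three-player corners are the doubled pairwise payoffs, ``W_tri`` is
    fixed, and ``G_tri = W_tri - alpha``.  The default payoff values give the
    pairwise game (T, R, P, S) = (1.1, 1, 0, -0.1) and the three-player corners
    (2.2, 2, 0, -0.2); sweeping ``alpha`` over [-1.4, 0.3] then spans the
    relaxed-to-strong dilemma landscape.
    """
    pairs = [("T_pair", T_pair), ("R_pair", R_pair), ("P_pair", P_pair), ("S_pair", S_pair)]
    for (na, va), (nb, vb) in zip(pairs, pairs[1:]):
        if not va > vb:
            raise ValueError(f"prisoner's dilemma ordering violated: {na} <= {nb}")
    return PayoffScheme(
        R_pair=R_pair,
        S_pair=S_pair,
        T_pair=T_pair,
        P_pair=P_pair,
        R_tri=2 * R_pair,
        S_tri=2 * S_pair,
        T_tri=2 * T_pair,
        P_tri=2 * P_pair,
        G_tri=W_tri - alpha,
        W_tri=W_tri,
    )


def pair_payoffs(s1: Strategy, s2: Strategy, scheme: PayoffScheme) -> tuple[float, float]:
    """Payoffs (row player, column player) of one two-player game."""
    m = {
        (C, C): (scheme.R_pair, scheme.R_pair),
        (C, D): (scheme.S_pair, scheme.T_pair),
        (D, C): (scheme.T_pair, scheme.S_pair),
        (D, D): (scheme.P_pair, scheme.P_pair),
    }
    return m[(s1, s2)]


def _tri_focal(s: Strategy, n_coop_partners: int, scheme: PayoffScheme) -> float:
    if s is C:
        return (scheme.S_tri, scheme.G_tri, scheme.R_tri)[n_coop_partners]
    return (scheme.P_tri, scheme.W_tri, scheme.T_tri)[n_coop_partners]


def triple_payoffs(
    s1: Strategy, s2: Strategy, s3: Strategy, scheme: PayoffScheme
) -> tuple[float, float, float]:
    """Payoffs of one three-player game, symmetric under player permutations.

    Unanimous groups earn the corner payoffs (R or P each; a lone deviator gets
    T or S); in split groups a cooperator facing one cooperator and one
    defector earns ``G_tri`` while a defector facing one of each earns
    ``W_tri``.
    """
    ss = (s1, s2, s3)
    n_coop = sum(1 for s in ss if s is C)
    return tuple(
        _tri_focal(s, n_coop - (1 if s is C else 0), scheme) for s in ss
    )  # type: ignore[return-value]


@dataclass(frozen=True)
class DilemmaReport:
    """Nash social-dilemma classification of a three-player scheme."""

    category: str  # "strong" | "relaxed" | "boundary"
    violated_conditions: tuple[str, ...]
    nash_equilibria_note: str


#: name -> predicate over a scheme; the Nash social-dilemma inequalities
DILEMMA_CONDITIONS = {
    # (a) a focal player gains when others cooperate, whatever it plays
    "partner_cooperation_helps_cooperator": lambda s: s.R_tri >= s.G_tri >= s.S_tri,
    "partner_cooperation_helps_defector": lambda s: s.T_tri >= s.W_tri >= s.P_tri,
    # (b) mutual cooperation beats mutual defection
    "mutual_cooperation_beats_mutual_defection": lambda s: s.R_tri > s.P_tri,
    # (c) inside any group, defectors out-earn cooperators
    "defector_beats_cooperators_in_single_defector_group": lambda s: s.T_tri > s.G_tri,
    "defector_beats_cooperator_in_two_defector_group": lambda s: s.W_tri > s.S_tri,
    # (d) unilaterally switching to defection always pays
    "defecting_from_full_cooperation_pays": lambda s: s.T_tri > s.R_tri,
    "defecting_in_split_group_pays": lambda s: s.W_tri > s.G_tri,
    "defecting_against_two_defectors_pays": lambda s: s.P_tri > s.S_tri,
}


def classify_dilemma(scheme: PayoffScheme) -> DilemmaReport:
    """Evaluate every Nash social-dilemma inequality and classify the game.

    ``G_tri < W_tri`` (alpha > 0): *strong* — all conditions hold and full
    defection is the only Nash equilibrium.  ``G_tri > W_tri`` (alpha < 0):
    *relaxed* — the defect-in-split-group condition fails and {C,C,D} becomes a
    second equilibrium.  Exact equality is flagged as a boundary case.
    """
    violated = tuple(
        name for name, pred in DILEMMA_CONDITIONS.items() if not pred(scheme)
    )
    if scheme.G_tri < scheme.W_tri:
        category = "strong"
        note = "full defection {D,D,D} is the unique Nash equilibrium"
    elif scheme.G_tri > scheme.W_tri:
        category = "relaxed"
        note = "Nash equilibria: full defection {D,D,D} and the split profile {C,C,D}"
    else:
        category = "boundary"
        note = "G_tri == W_tri: neither strictly strong nor strictly relaxed"
    return DilemmaReport(category, violated, note)


def total_payoff(h, state, node: int, scheme: PayoffScheme) -> float:
    """Accumulated payoff of ``node`` over all its games in both layers.

    Pairwise games use each participant's pairwise-slot strategy, triangle
    games the triangle-slot strategy; in scalar mode the single slot serves
    both orders.
    """
    s_pair = state.pair_strategy
    s_tri = state.tri_strategy
    me_pair = INT_TO_STRATEGY[int(s_pair[node])]
    me_tri = INT_TO_STRATEGY[int(s_tri[node])]
    pi = 0.0
    for j in h.pair_neighbors(node):
        pi += pair_payoffs(me_pair, INT_TO_STRATEGY[int(s_pair[j])], scheme)[0]
    for t in h.triangles_of(node):
        n_coop = sum(1 for v in t if v != node and s_tri[v] == 1)
        pi += _tri_focal(me_tri, n_coop, scheme)
    return pi
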