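# Methods

## Model

A population of `N` players is a hypergraph with hyperedges of sizes 2 and 3
only: a pairwise layer `E_pair` and a triangle layer `E_tri`. Every player
holds one strategy per interaction order, `s_i = (s_i_pair, s_i_tri)`, each
either cooperate (C) or defect (D); a scalar baseline mode gives each player a
single strategy used at both orders.

**Games.** Pairwise games are a prisoner's dilemma with
`(T, R, P, S) = (1.1, 1, 0, -0.1)` (defaults; any ordering-respecting values
are accepted). Three-player games are a symmetric 2x2x2 payoff cube. A focal
player's cube payoff depends only on its own strategy and the number of
cooperating partners: a cooperator earns `R_tri / G_tri / S_tri` against
2/1/0 cooperating partners, a defector `T_tri / W_tri / P_tri`. The corner
entries are tied to the pairwise game by the comparability rule
`X_tri = 2 X_pair` for `X in {R, S, T, P}`, so a triangle of unanimous
partners is worth exactly two pair games and group size confers no synergistic
bonus. The two genuinely multi-player entries are controlled by the dilemma
strength `alpha = W_tri - G_tri` with `W_tri = 0.7` fixed and
`G_tri = W_tri - alpha`. For `alpha > 0` all Nash social-dilemma inequalities
hold (*strong* dilemma, unique equilibrium all-D); for `alpha < 0` defecting
in a split group no longer pays and {C,C,D} becomes a second equilibrium
(*relaxed*). `classify_dilemma` evaluates all eight inequalities; note that
for `alpha < -1.3` the monotonicity condition `R_tri >= G_tri` also breaks
(`G_tri > 2`), which the report flags but the constructor permits, since the
interesting sweep range extends to `alpha = -1.4`.

**Structure.** `build_full_overlap` samples a three-regular simplicial complex
by configuration-model stub matching: each node contributes `k_tri` stubs,
shuffled and cut into triples; a matching is rejected if a triple repeats a
node, duplicates a triangle, shares two nodes with an existing triangle (which
would project a duplicate edge), or leaves a layer disconnected. Restarts are
cheap (rejection is rare for `N >= 100`; the budget is 1000 attempts). The
pairwise layer is then the exact triangle projection, every pairwise degree is
`2 k_tri`, and the topological overlap
`omega = |E_pair ∩ proj(E_tri)| / |E_pair|` equals 1.

Overlap is lowered by criss-cross double edge swaps (A-B, C-D -> A-D, B-C)
that preserve all pairwise degrees and never touch triangles. Candidate edge
pairs are drawn uniformly (with a random orientation of the second edge), but
a candidate is accepted only if it does not increase the distance
`|omega - target|`. The directed acceptance is necessary, not cosmetic: blind
swapping relaxes to the coincidental overlap of a random 4-regular graph
(about 0.013 at N=300), so small targets such as `omega = 0` are unreachable
without it. Pairwise connectivity is re-checked after every committed swap by
breadth-first search and disconnecting swaps are reverted; the triangle layer
is verified once (it never changes). Achievable overlap values are multiples
of `1/|E_pair|`, which is also the default tolerance.

**Dynamics.** An elementary update draws a uniform focal player and a uniform
model among the focal's de-duplicated co-players across both layers (an
alternative `layer_then_neighbour` rule — pick a layer, then a co-player in
it — is available; the two differ only at intermediate overlap). Both players
accumulate payoffs over *all* their games in both layers; payoffs are
recomputed from scratch at every update. The focal then copies exactly one
strategy slot of the model with the Fermi probability
`1/(1 + exp(-w (pi_m - pi_f)))`: the target slot is chosen uniformly (the 1/2
factor) and the source is the model's other-order slot with probability
`pswitch`. The five outcome probabilities (four copy events plus no change)
sum to one for any Fermi value and coupling. The random-draw order is fixed —
focal, model, target slot, source order, acceptance — so runs are reproducible
from a seed. One MCS is `2N` elementary updates (each slot updated once on
average); the scalar mode uses `N` single-slot updates per MCS. The default
noise is `w = 1/(k_pair + k_tri)`, computed from the configured degrees.

**Quasi-stationary evolution.** Homogeneous configurations absorb the
imitation dynamics, so stationary densities are measured conditioned on
survival: after every MCS the state is checked against the absorbing trigger
and, when absorbed, replaced by a snapshot from a reservoir of previously
visited active states, sampled proportionally to dwell weight. Two triggers
are implemented: `either_layer` (default) teleports as soon as one layer is
strategy-homogeneous; `joint` only when no elementary update can change the
state (all `2N` slots equal when `pswitch > 0`; each layer homogeneous when
`pswitch = 0`). The reservoir holds at most `capacity` snapshots recorded
every `cadence` MCS; past capacity each new record overwrites a uniformly
chosen slot, giving the store an exponentially decaying memory of roughly
`capacity * cadence` MCS. Defaults are capacity 20, cadence 1. The memory must
be short: the hovering distributions sit close to the absorbing boundaries,
and a long memory re-injects stale transient states, biasing layer densities
away from the boundary (with uniform-over-all-history inclusion the
triangle-layer density at the decoupled plateau drops from ~0.93 to ~0.80 at
N=300). The evolution seeds the reservoir with the (active) initial state so
a teleport target always exists; the bare reservoir still refuses absorbing
records and errors on an empty teleport.

## Experiment conventions

Default configuration: `N = 1500`, `k_pair = 4`, `k_tri = 2`, `10^5` MCS with
the last `10^4` as the stationary window, `M = 400` independent runs,
`rho0_pair = rho0_tri = 0.5`. The test suite and the acceptance script use the
desk-scale variant `N = 300` (divisible by 3), `2x10^4` MCS, window `2x10^3`,
`M = 20`, which runs in seconds per run on one CPU. Initial cooperators are
placed by exact count (`round(rho0 * N)` per slot type, uniformly without
replacement, independently per slot). Every run regenerates and rewires its
own hypergraph from its run seed, so ensembles average over structural and
dynamical randomness; per-run seeds are spawned from the master seed with
numpy's `SeedSequence`. Sweep grids reuse the master seed at every grid point,
which makes tables byte-reproducible and lets parameters that a mode ignores
(e.g. `pswitch` in scalar mode) reproduce identical rows.

The long-run engine is a numba kernel implementing exactly the update rule
above over packed integer arrays (~200 ns per elementary update); a pure-Python
path implements the same rule object-by-object and is used by the unit tests
and small systems. Both engines are validated against an exact oracle: for
systems with at most 12 strategy slots, `exact_small_system_oracle` builds the
full one-step transition matrix analytically and solves absorption
probabilities by linear algebra; simulated fixation frequencies from both
engines agree with the exact values within three standard errors, and with
all payoffs equal the all-C fixation probability reproduces the neutral
martingale (initial cooperator fraction) to 1e-9.

## Numerical choices

- Fermi evaluation is overflow-safe (branch on the sign of the exponent).
- Payoff equality checks in tests use absolute tolerance 1e-12 (all default
  payoffs are short decimals).
- Overlap comparisons allow `tolerance + 1e-9` to absorb float noise at the
  one-edge granularity.
- The rewiring swap budget defaults to `100 |E_pair|` attempts; failure to
  reach the target raises with the best overlap achieved.
- Absorption is checked once per MCS (the observables are per-MCS; checking
  per elementary update was measured and changes the plateau densities by
  under 0.03 without improving them).

## What the generator emulates, and what it does not

Synthetic structures are random-regular: every node has exactly the same
pairwise degree and triangle membership, and overlap is the only structural
dial. Real interaction data have heterogeneous and correlated hyperdegrees,
degree–degree correlations, and community structure, none of which is modelled
here; conclusions from passing tests are about the idealized regular ensemble
only. Hyperedges larger than three players, weighted or directed interactions,
payoff noise, and synergistic (non-linear) group scaling are out of scope.

## Behaviour of the stationary regimes, and a known limitation

At the decoupled point (`pswitch = 0`, relaxed dilemma `alpha = -0.5`) the two
layers separate: the pairwise layer hovers just above its all-defect boundary
and the triangle layer just below its all-cooperate boundary, so the overall
density sits near 1/2 at every overlap — the package reproduces this plateau
at both desk scale (pair ~0.04, triangle ~0.93 at N=300) and full scale (pair
<0.01, triangle >0.99 at N=1500). The hover gap scales like `1/N`: the
surviving-defector load under quasi-stationary conditioning is a roughly
N-independent 15–25 slots, which desk-scale expectations must account for.
Deep in the relaxed regime (`alpha <= -1`) any positive coupling drives the
system to full cooperation, and in the strong-dilemma regime
(`alpha > 0`) defectors dominate with residual cooperation of a few percent.

Between those extremes this implementation places the cooperative phase
boundary near `alpha ~ -0.9` at high coupling: at moderate dilemma strength
(e.g. `alpha = -0.5`) with strong coupling and high overlap the quasi-
stationary state is defection-dominated, because a lone defector out-earns
cooperators at every overlap (`T > R` at both orders) and the split-group
advantage `G > W` is too weak at `w = 1/6` to halt invasion — verified by
direct stability probes from near-full cooperation and by exhaustive variants
of the update rule (slot-resolved payoff comparisons, vector copying,
per-update absorption checks, both triggers, all reservoir laws). Reports of
substantially larger cooperative regions for this class of model at high
coupling could not be reproduced by any reading of the update rule
implemented here; treat the high-coupling/moderate-dilemma regime as
implementation-sensitive when comparing across codes.
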