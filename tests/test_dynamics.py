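"""Fermi rule, focal/model selection, and the coupled two-slot update."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hypercoop import (
    DynamicsConfig,
    StrategyState,
    build_full_overlap,
    elementary_update,
    fermi_probability,
    is_absorbing,
    make_scheme,
    monte_carlo_step,
    outcome_probabilities,
    pick_focal_and_model,
    rewire_to_overlap,
    scalar_update,
)

from conftest import mixed_state


class TestFermiProbability:
    def test_equal_payoffs_give_half(self):
        assert fermi_probability(3.2, 3.2, 1 / 6) == 0.5

    def test_zero_noise_is_a_coin_flip(self):
        assert fermi_probability(100.0, -5.0, 0.0) == 0.5

    def test_quoted_value(self):
        # payoff gap 2 at noise 1/6: 1/(1+exp(-1/3))
        assert fermi_probability(2.0, 0.0, 1 / 6) == pytest.approx(0.5825702, abs=1e-6)

    def test_overflow_safe_at_extreme_gaps(self):
        assert fermi_probability(1e6, 0.0, 10.0) == pytest.approx(1.0)
        assert fermi_probability(-1e6, 0.0, 10.0) == pytest.approx(0.0)

    @given(
        st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0, 5, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_complementarity_and_monotonicity(self, a, b, w):
        p = fermi_probability(a, b, w)
        assert 0.0 <= p <= 1.0
        assert p + fermi_probability(b, a, w) == pytest.approx(1.0)
        if a > b:
            assert p >= 0.5


class TestOutcomeProbabilities:
    @pytest.mark.parametrize("prob", [0.0, 0.3, 0.5, 1.0])
    @pytest.mark.parametrize("pswitch", [0.0, 0.2, 0.5, 0.9, 1.0])
    def test_five_outcomes_normalize(self, prob, pswitch):
        probs = outcome_probabilities(prob, pswitch)
        assert len(probs) == 5
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_cross_copy_without_coupling(self):
        probs = outcome_probabilities(0.8, 0.0)
        assert probs["pair<-tri"] == 0.0
        assert probs["tri<-pair"] == 0.0

    def test_only_cross_copy_at_full_coupling(self):
        probs = outcome_probabilities(0.8, 1.0)
        assert probs["pair<-pair"] == 0.0
        assert probs["tri<-tri"] == 0.0


class TestPickFocalAndModel:
    def test_full_overlap_model_among_four_coplayers(self, full_overlap_300, rng):
        for _ in range(200):
            f, m = pick_focal_and_model(full_overlap_300, rng)
            assert m in full_overlap_300.pair_neighbors(f)
            assert m != f

    def test_zero_overlap_model_uniform_over_eight(self, full_overlap_300):
        h = rewire_to_overlap(full_overlap_300, 0.0, tolerance=0.01, seed=4)
        rng = np.random.default_rng(0)
        focal = 0
        pool = sorted(h.pair_neighbors(focal) | h.triangle_partners(focal))
        assert len(pool) == 8
        counts = dict.fromkeys(pool, 0)
        n_draws = 0
        while n_draws < 100_000:
            f, m = pick_focal_and_model(h, rng)
            if f == focal:
                counts[m] += 1
                n_draws += 1
        observed = np.array([counts[m] for m in pool])
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.01

    def test_two_node_toy_is_deterministic(self, rng):
        from hypercoop import Hypergraph

        h = Hypergraph(2, pair_edges={(0, 1)})
        f, m = pick_focal_and_model(h, rng)
        assert {f, m} == {0, 1}


class TestElementaryUpdate:
    def test_no_cross_copies_when_decoupled(self, triangle_toy, default_scheme, rng):
        cfg = DynamicsConfig(w=1 / 6, pswitch=0.0)
        state = mixed_state(3, rng)
        for _ in range(500):
            ev = elementary_update(triangle_toy, state, default_scheme, cfg, rng)
            assert ev.source_slot == ev.target_slot

    def test_only_cross_copies_at_full_coupling(self, triangle_toy, default_scheme, rng):
        cfg = DynamicsConfig(w=1 / 6, pswitch=1.0)
        state = mixed_state(3, rng)
        for _ in range(500):
            ev = elementary_update(triangle_toy, state, default_scheme, cfg, rng)
            assert ev.source_slot != ev.target_slot

    def test_cross_copy_frequency_matches_coupling(self, triangle_toy, default_scheme):
        """Among accepted imitations the cross-order fraction estimates pswitch."""
        pswitch = 0.3
        cfg = DynamicsConfig(w=1 / 6, pswitch=pswitch)
        rng = np.random.default_rng(7)
        n_accepted = 0
        n_cross = 0
        state = mixed_state(3, rng)
        for _ in range(100_000):
            ev = elementary_update(triangle_toy, state, default_scheme, cfg, rng)
            if ev.accepted:
                n_accepted += 1
                n_cross += ev.source_slot != ev.target_slot
        # binomial 99% CI around pswitch
        half_width = 2.576 * np.sqrt(pswitch * (1 - pswitch) / n_accepted)
        assert abs(n_cross / n_accepted - pswitch) < half_width

    def test_at_most_one_slot_changes(self, triangle_toy, default_scheme, rng):
        cfg = DynamicsConfig(w=1 / 6, pswitch=0.5)
        state = mixed_state(3, rng)
        for _ in range(500):
            before_p, before_t = state.pair.copy(), state.tri.copy()
            elementary_update(triangle_toy, state, default_scheme, cfg, rng)
            changed = int((state.pair != before_p).sum()) + int((state.tri != before_t).sum())
            assert changed <= 1


class TestScalarUpdate:
    def test_identical_strategies_never_change_state(self, triangle_toy, default_scheme, rng):
        cfg = DynamicsConfig(w=1 / 6, mode="scalar")
        state = StrategyState("scalar", slot=np.array([1, 1, 1], np.int8))
        for _ in range(100):
            scalar_update(triangle_toy, state, default_scheme, cfg, rng)
        assert state.slot.tolist() == [1, 1, 1]

    def test_equal_payoffs_accepted_half_the_time(self, triangle_toy, rng):
        from hypercoop.games import PayoffScheme

        neutral = PayoffScheme(*([1.0] * 10))
        cfg = DynamicsConfig(w=1 / 6, mode="scalar")
        state = StrategyState("scalar", slot=np.array([1, 0, 1], np.int8))
        probs = [
            scalar_update(triangle_toy, state.copy(), neutral, cfg, rng).fermi_prob
            for _ in range(50)
        ]
        assert all(p == 0.5 for p in probs)

    def test_all_defect_is_absorbing(self, triangle_toy, default_scheme, rng):
        cfg = DynamicsConfig(w=1 / 6, mode="scalar")
        state = StrategyState("scalar", slot=np.zeros(3, np.int8))
        for _ in range(200):
            scalar_update(triangle_toy, state, default_scheme, cfg, rng)
        assert state.slot.sum() == 0


class TestMonteCarloStep:
    def test_vector_mcs_runs_2n_updates(self, triangle_toy, default_scheme, monkeypatch):
        import hypercoop.dynamics as dyn

        calls = {"n": 0}
        orig = dyn.elementary_update

        def counting(*args, **kw):
            calls["n"] += 1
            return orig(*args, **kw)

        monkeypatch.setattr(dyn, "elementary_update", counting)
        rng = np.random.default_rng(0)
        state = mixed_state(3, rng)
        cfg = DynamicsConfig(w=1 / 6, pswitch=0.5)
        monte_carlo_step(triangle_toy, state, default_scheme, cfg, rng)
        assert calls["n"] == 6

    def test_frozen_all_cooperate_state_is_invariant(self, triangle_toy, default_scheme, rng):
        cfg = DynamicsConfig(w=1 / 6, pswitch=0.5)
        state = StrategyState("vector", pair=np.ones(3, np.int8), tri=np.ones(3, np.int8))
        for _ in range(20):
            monte_carlo_step(triangle_toy, state, default_scheme, cfg, rng)
        assert state.pair.sum() == 3 and state.tri.sum() == 3

    def test_neutral_dynamics_has_no_density_drift(self):
        """At zero noise copying is unbiased: density fluctuates around 1/2."""
        from hypercoop import ExperimentConfig, evolve_quasistationary
        from hypercoop.experiments import build_structure, initialize_state

        cfg = ExperimentConfig.scaled_down(n_nodes=30, pswitch=0.5, w=0.0)
        rng = np.random.default_rng(3)
        h = build_structure(cfg, rng)
        state = initialize_state(30, 0.5, 0.5, "vector", rng)
        traj = evolve_quasistationary(
            h, state, cfg.scheme(), cfg.dynamics_config(), 10_000, rng=rng
        )
        assert abs(traj.rho.mean() - 0.5) < 0.1


class TestIsAbsorbing:
    def test_all_cooperators_absorbing_under_both_triggers(self):
        state = StrategyState("vector", pair=np.ones(4, np.int8), tri=np.ones(4, np.int8))
        for trigger in ("either_layer", "joint"):
            cfg = DynamicsConfig(w=0.1, pswitch=0.5, absorbing_trigger=trigger)
            assert is_absorbing(state, cfg)

    def test_one_homogeneous_layer_triggers_either_layer(self):
        state = StrategyState(
            "vector", pair=np.zeros(4, np.int8), tri=np.array([1, 0, 1, 0], np.int8)
        )
        cfg = DynamicsConfig(w=0.1, pswitch=0.5, absorbing_trigger="either_layer")
        assert is_absorbing(state, cfg)

    def test_one_homogeneous_layer_not_joint_absorbing_when_coupled(self):
        # a cross-order copy can still rewrite a pair slot from a tri slot
        state = StrategyState(
            "vector", pair=np.zeros(4, np.int8), tri=np.array([1, 0, 1, 0], np.int8)
        )
        cfg = DynamicsConfig(w=0.1, pswitch=0.5, absorbing_trigger="joint")
        assert not is_absorbing(state, cfg)

    def test_decoupled_joint_trigger_needs_each_layer_homogeneous(self):
        pair = np.zeros(4, np.int8)
        tri = np.ones(4, np.int8)
        state = StrategyState("vector", pair=pair, tri=tri)
        cfg = DynamicsConfig(w=0.1, pswitch=0.0, absorbing_trigger="joint")
        assert is_absorbing(state, cfg)

    def test_scalar_mode(self):
        cfg = DynamicsConfig(w=0.1, mode="scalar")
        assert is_absorbing(StrategyState("scalar", slot=np.zeros(5, np.int8)), cfg)
        assert not is_absorbing(StrategyState("scalar", slot=np.array([0, 1], np.int8)), cfg)
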