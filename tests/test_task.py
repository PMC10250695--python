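import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arbitrl.task import (
    ACTIONS,
    GOAL_COLORS,
    LIKELY_P,
    TRIAL_RANGE,
    TopologyConfig,
    TrialRecord,
    generate_schedule,
    generate_training_schedule,
    generate_tree,
    optimal_policy_value,
    payout,
    sample_transition,
)

from _oracles import best_contingent_value, best_fixed_sequence_value


class TestGenerateTree:
    def test_default_config_pair_count(self, tree):
        # 1 root + 4 stage-2 states, 2 actions each => 10 pairs, 2 successors each
        pairs = [(s, a) for s in tree.nonterminal_states() for a in ACTIONS]
        assert len(pairs) == 10
        for pair in pairs:
            assert len(tree.successors[pair]) == 2

    def test_successors_in_next_stage(self, tree):
        for (s, a), (u, v) in tree.successors.items():
            assert tree.stage_of(u) == tree.stage_of(s) + 1
            assert tree.stage_of(v) == tree.stage_of(s) + 1
            assert u != v

    def test_terminal_labels(self, tree):
        values = sorted(tree.terminal_value.values())
        assert values == [0, 0, 10, 10, 20, 20, 40, 40]
        for t in tree.stage3_states:
            color, value = tree.terminal_color[t], tree.terminal_value[t]
            assert (value == 0) == (color == "gray")

    def test_every_goal_color_reachable(self):
        for seed in range(25):
            assert set(GOAL_COLORS) <= generate_tree(seed).reachable_colors()

    def test_same_seed_identical(self):
        t1, t2 = generate_tree(42), generate_tree(42)
        assert t1.successors == t2.successors
        assert t1.terminal_color == t2.terminal_color

    def test_different_seed_differs(self):
        assert generate_tree(1).successors != generate_tree(2).successors

    def test_config_without_blue_rejected(self):
        with pytest.raises(ValueError, match="blue"):
            TopologyConfig(terminal_labels=("gray",) * 2 + ("yellow",) * 3 + ("red",) * 3)

    def test_custom_topology(self):
        cfg = TopologyConfig(
            n_stage2=3, n_stage3=6,
            terminal_labels=("gray", "gray", "yellow", "red", "blue", "blue"),
        )
        t = generate_tree(7, cfg)
        assert len(list(t.stage2_states)) == 3
        assert len(list(t.stage3_states)) == 6
        t.validate()


class TestSchedule:
    def test_block_counts(self):
        sched = generate_schedule(0)
        assert len(sched.blocks) == 56
        counts = collections.Counter((b.condition, b.uncertainty) for b in sched.blocks)
        assert set(counts.values()) == {14}

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_invariants_any_seed(self, seed):
        sched = generate_schedule(seed)
        assert len(sched.blocks) == 56
        counts = collections.Counter((b.condition, b.uncertainty) for b in sched.blocks)
        assert all(v == 14 for v in counts.values())
        for b in sched.blocks:
            lo, hi = TRIAL_RANGE[b.uncertainty]
            assert lo <= b.n_trials <= hi
            if b.condition == "specific":
                assert b.goal_color in GOAL_COLORS
            else:
                assert b.goal_color is None

    def test_mean_total_trials_close_to_280(self):
        totals = [generate_schedule(s).n_trials for s in range(300)]
        assert abs(np.mean(totals) - 280) < 2

    def test_deterministic(self):
        assert generate_schedule(9).blocks == generate_schedule(9).blocks

    def test_training_phase(self):
        sched = generate_training_schedule(3)
        conds = [b.condition for b in sched.blocks for _ in range(b.n_trials)]
        assert conds.count("flexible") == 80
        assert conds.count("specific") == 20
        # all flexible trials precede all specific trials
        assert conds == ["flexible"] * 80 + ["specific"] * 20
        assert sched.phase == "training"


class TestSampleTransition:
    @pytest.mark.parametrize("uncertainty", ["low", "high"])
    def test_empirical_frequency(self, tree, rng, uncertainty):
        likely = tree.successors[(0, 0)][0]
        n = 10_000
        hits = sum(
            sample_transition(tree, 0, 0, uncertainty, rng) == likely for _ in range(n)
        )
        p = LIKELY_P[uncertainty]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_only_candidates_sampled(self, tree, rng):
        candidates = set(tree.successors[(2, 1)])
        for _ in range(200):
            assert sample_transition(tree, 2, 1, "high", rng) in candidates

    def test_terminal_state_errors(self, tree, rng):
        with pytest.raises(ValueError, match="terminal"):
            sample_transition(tree, tree.n_stage2 + 1, 0, "low", rng)


class TestPayout:
    def test_flexible_pays_coins_shown(self, tree):
        for t in tree.stage3_states:
            assert payout(tree, t, "flexible", None) == tree.terminal_value[t]

    def test_specific_gates_by_color(self, tree):
        for t in tree.stage3_states:
            for goal in GOAL_COLORS:
                paid = payout(tree, t, "specific", goal)
                if tree.terminal_color[t] == goal:
                    assert paid == tree.terminal_value[t]
                else:
                    assert paid == 0

    def test_paid_never_exceeds_shown(self, tree):
        for t in tree.stage3_states:
            for goal in GOAL_COLORS:
                assert payout(tree, t, "specific", goal) <= tree.terminal_value[t]


class TestOptimalPolicyValue:
    def test_toy_hand_computed(self, toy_tree):
        # flexible, low uncertainty: expected rewards worked out by hand
        q, opt = optimal_policy_value(toy_tree, "flexible", None, "low")
        assert q[(1, 0)] == pytest.approx(36.0)
        assert q[(1, 1)] == pytest.approx(4.0)
        assert q[(2, 0)] == pytest.approx(11.0)
        assert q[(2, 1)] == pytest.approx(19.0)
        assert q[(0, 0)] == pytest.approx(34.3)
        assert q[(0, 1)] == pytest.approx(20.7)
        assert opt[0] == (0,)
        assert opt[1] == (0,)
        assert opt[2] == (1,)

    def test_specific_goal_bounds_root_value(self, tree):
        # a goal labeling only 10-coin terminals cannot be worth more than 10
        q, _ = optimal_policy_value(tree, "specific", "yellow", "low")
        assert max(q[(0, 0)], q[(0, 1)]) <= 10 + 1e-9

    def test_all_equal_terminals_tie(self, toy_tree):
        from dataclasses import replace

        flat = replace(
            toy_tree,
            terminal_value={3: 20, 4: 20, 5: 20, 6: 20},
            terminal_color={t: "red" for t in (3, 4, 5, 6)},
        )
        _, opt = optimal_policy_value(flat, "flexible", None, "high")
        assert all(opt[s] == (0, 1) for s in flat.nonterminal_states())

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_contingent_policy_enumeration(self, seed):
        tree = generate_tree(seed)
        for condition, goals in (("flexible", [None]), ("specific", list(GOAL_COLORS))):
            for goal in goals:
                for uncertainty in ("low", "high"):
                    q, _ = optimal_policy_value(tree, condition, goal, uncertainty)
                    root = max(q[(0, 0)], q[(0, 1)])
                    oracle = best_contingent_value(tree, condition, goal, uncertainty)
                    assert root == pytest.approx(oracle, abs=1e-9)
                    # fixed (a1, a2) sequences can only do worse or equal
                    assert best_fixed_sequence_value(
                        tree, condition, goal, uncertainty
                    ) <= root + 1e-9


class TestTrialRecordValidation:
    def test_valid_session_passes(self, tree, mb_session):
        for tr in mb_session:
            tr.validate(tree)

    def test_bad_transition_rejected(self, tree, mb_session):
        import copy

        tr = copy.deepcopy(next(t for t in mb_session if not t.missing))
        candidates = tree.successors[(tr.s1, tr.a1)]
        tr.s2 = next(s for s in tree.stage2_states if s not in candidates)
        with pytest.raises(ValueError, match="not a successor"):
            tr.validate(tree)

    def test_reward_rule_enforced(self, tree, mb_session):
        import copy

        tr = copy.deepcopy(next(t for t in mb_session if not t.missing))
        tr.reward_paid = tr.coins_shown + 10
        with pytest.raises(ValueError, match="reward_paid|coins"):
            tr.validate(tree)

    def test_reward_never_exceeds_coins(self, mb_session):
        for tr in mb_session:
            assert tr.reward_paid <= tr.coins_shown
            if tr.condition == "flexible" and not tr.missing:
                assert tr.reward_paid == tr.coins_shown
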