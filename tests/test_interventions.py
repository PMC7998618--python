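"""Edge regulation profiles, influence index, walk simulation, switching
times, and the statistical intervention classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbnet.interventions import (
    InterventionSpec,
    SwitchTimeDistribution,
    apply_intervention,
    compare_interventions,
    edge_regulation_profile,
    first_switch_time,
    influence_index,
    measure_switch_times,
    module_activation,
    simulate_walk,
)
from pbnet.rules import ProbabilisticRule, RuleSet


def _rule(target, regs, table):
    return ProbabilisticRule(target, regs, np.asarray(table, float), np.zeros(len(table)))


class TestEdgeRegulationProfile:
    def test_or_and_worked_example(self, worked_rule):
        p = edge_regulation_profile(worked_rule, "A")
        assert p.avg_on == 1.0
        assert p.avg_off == 0.25
        assert p.sign == "positive"
        assert p.non == 0.75 and p.son == 1.0
        assert p.noff == 0.0 and p.soff == 0.0

    def test_negation_rule_negative_branch(self):
        p = edge_regulation_profile(_rule("T", ("A",), [1.0, 0.0]), "A")
        assert p.sign == "negative"
        assert p.noff == 1.0 and p.soff == 1.0
        assert p.non == 0.0 and p.son == 0.0

    def test_ignored_regulator_scores_zero(self):
        p = edge_regulation_profile(_rule("T", ("A", "B"), [0.3, 0.7, 0.3, 0.7]), "A")
        assert p.sign == "none"
        assert p.non == p.son == p.noff == p.soff == 0.0

    def test_non_regulator_rejected(self, worked_rule):
        with pytest.raises(KeyError):
            edge_regulation_profile(worked_rule, "Z")

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    @settings(deadline=None)
    def test_score_invariants(self, table):
        p = edge_regulation_profile(_rule("T", ("A", "B"), table), "A")
        for v in (p.non, p.son, p.noff, p.soff):
            assert 0 <= v <= 1
        # exactly one of the ON/OFF pairs can be nonzero
        assert p.non + p.son == 0 or p.noff + p.soff == 0


class TestInfluenceIndex:
    def _system(self):
        rules = {"T": _rule("T", ("K",), [0.0, 1.0])}
        modules = {"T": "m1", "K": "unassigned"}
        return rules, modules

    def test_ko_down_on_necessary_sufficient_edge(self):
        rules, modules = self._system()
        assert influence_index("K", "KO", "DOWN", "m1", rules, modules) == 1.5

    def test_ko_up_is_antisymmetric(self):
        rules, modules = self._system()
        assert influence_index("K", "KO", "UP", "m1", rules, modules) == -1.5

    def test_no_module_targets_scores_zero(self):
        rules, modules = self._system()
        assert influence_index("K", "KO", "DOWN", "m2", rules, modules) == 0.0

    def test_invalid_mode_or_goal(self):
        rules, modules = self._system()
        with pytest.raises(ValueError):
            influence_index("K", "XX", "DOWN", "m1", rules, modules)
        with pytest.raises(ValueError):
            influence_index("K", "KO", "SIDEWAYS", "m1", rules, modules)

    @given(st.integers(0, 500))
    @settings(deadline=None, max_examples=25)
    def test_antisymmetry_random_rulesets(self, seed):
        rng = np.random.default_rng(seed)
        rules = {
            f"T{i}": _rule(f"T{i}", ("K", f"R{i}"), rng.random(4))
            for i in range(3)
        }
        modules = {f"T{i}": "m1" for i in range(3)}
        for mode in ("KO", "CA"):
            down = influence_index("K", mode, "DOWN", "m1", rules, modules)
            up = influence_index("K", mode, "UP", "m1", rules, modules)
            assert down == pytest.approx(-up)


class TestApplyIntervention:
    def _ruleset(self):
        return RuleSet(
            rules={
                "X_T": _rule("X_T", ("S",), [0.1, 0.9]),
                "X_A": ProbabilisticRule.from_truth_table("X_A", ("X_T",), [0, 1]),
                "Y": _rule("Y", ("X_A",), [0.2, 0.8]),
            },
            source_nodes={"S"},
        )

    def test_ko_pins_both_forms(self):
        constrained, held = apply_intervention(
            self._ruleset(), InterventionSpec(targets=(("X", "KO"),))
        )
        assert held == {"X_T": 0, "X_A": 0}
        assert constrained.rules["X_T"].table.tolist() == [0.0]
        assert constrained.rules["X_A"].table.tolist() == [0.0]

    def test_empty_spec_is_wild_type(self):
        rs = self._ruleset()
        constrained, held = apply_intervention(rs, InterventionSpec())
        assert held == {}
        assert set(constrained.rules) == set(rs.rules)

    def test_ca_of_source_equals_pinning_on(self):
        constrained, held = apply_intervention(
            self._ruleset(), InterventionSpec(targets=(("S", "CA"),))
        )
        assert held == {"S": 1}
        assert "S" not in constrained.source_nodes
        assert constrained.rules["S"].table.tolist() == [1.0]

    def test_duplicate_target_rejected(self):
        with pytest.raises(ValueError):
            InterventionSpec(targets=(("X", "KO"), ("X", "CA")))

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            apply_intervention(self._ruleset(), InterventionSpec(targets=(("Q", "KO"),)))


class TestSimulateWalk:
    def test_absorbing_all_on_state(self):
        rs = RuleSet(
            rules={
                "A": ProbabilisticRule.from_truth_table("A", (), [1.0]),
                "B": ProbabilisticRule.from_truth_table("B", (), [1.0]),
            }
        )
        walk = simulate_walk(rs, {"A": 1, "B": 1}, n_steps=200, rng_seed=0)
        assert (walk.to_numpy() == 1).all()

    def test_held_ko_node_stays_off(self):
        rs = RuleSet(
            rules={
                "A": ProbabilisticRule.from_truth_table("A", (), [1.0]),
                "B": _rule("B", ("A",), [0.5, 0.5]),
            }
        )
        walk = simulate_walk(rs, {"A": 1, "B": 1}, n_steps=500, rng_seed=1,
                             held={"A": 0})
        assert (walk["A"].to_numpy() == 0).all()

    def test_fair_coin_rule_matches_binomial(self):
        rs = RuleSet(rules={"A": _rule("A", ("A",), [0.5, 0.5])})
        walk = simulate_walk(rs, {"A": 0}, n_steps=10_000, rng_seed=42)
        frac = walk["A"].to_numpy()[1:].mean()
        sigma = 0.5 / np.sqrt(10_000)
        assert abs(frac - 0.5) < 3 * sigma

    def test_deterministic_given_seed(self):
        rs = RuleSet(rules={"A": _rule("A", ("A",), [0.3, 0.8])})
        a = simulate_walk(rs, {"A": 0}, n_steps=100, rng_seed=5)
        b = simulate_walk(rs, {"A": 0}, n_steps=100, rng_seed=5)
        assert a.equals(b)


class TestModuleActivation:
    def test_bands(self):
        module = ["A", "B", "C", "D"]
        state = dict.fromkeys(module, 0)
        assert module_activation(state, module, set()) == (0.0, "low")
        state.update({"A": 1, "B": 1})
        assert module_activation(state, module, set()) == (0.5, "intermediate")
        state.update({"C": 1, "D": 1})
        assert module_activation(state, module, set()) == (1.0, "high")

    def test_quarter_boundary_is_intermediate(self):
        module = ["A", "B", "C", "D"]
        state = {"A": 1, "B": 0, "C": 0, "D": 0}
        frac, band = module_activation(state, module, set())
        assert frac == 0.25 and band == "intermediate"

    def test_source_only_module_rejected(self):
        with pytest.raises(ValueError):
            module_activation({"A": 1}, ["A"], {"A"})


class TestFirstSwitchTime:
    def _walk(self, fracs, module=("A", "B", "C", "D")):
        import pandas as pd

        n_on = [int(round(f * len(module))) for f in fracs]
        rows = [[1] * k + [0] * (len(module) - k) for k in n_on]
        return pd.DataFrame(rows, columns=list(module))

    def test_immediate_switch(self):
        walk = self._walk([0.0, 0.5, 0.5])
        assert first_switch_time(walk, list(walk.columns), set(), "low") == 1

    def test_censored_at_steps_plus_one(self):
        walk = self._walk([0.0] * 11)
        assert first_switch_time(walk, list(walk.columns), set(), "low") == 11

    def test_intermediate_to_low(self):
        walk = self._walk([0.5, 0.5, 0.0, 0.5])
        assert first_switch_time(walk, list(walk.columns), set(), "intermediate") == 2

    def test_truncation_only_censors(self):
        walk = self._walk([0.0, 0.0, 0.0, 0.5, 0.0])
        full = first_switch_time(walk, list(walk.columns), set(), "low")
        trunc = first_switch_time(walk.iloc[:3], list(walk.columns), set(), "low")
        assert full == 3
        assert trunc == 3  # censored value = truncated length


class TestMeasureSwitchTimes:
    def test_directions_and_censoring(self):
        # module copies a held source: with S=1 the module fills up fast
        rs = RuleSet(
            rules={m: _rule(m, ("S",), [0.0, 1.0]) for m in ("A", "B", "C", "D")},
            source_nodes={"S"},
        )
        start = {"S": 1, "A": 0, "B": 0, "C": 0, "D": 0}
        dist = measure_switch_times(rs, start, ["A", "B", "C", "D"], {"S"},
                                    n_walks=20, n_steps=200, master_seed=1)
        assert dist.direction == "low->intermediate"
        assert all(1 <= t <= 201 for t in dist.times)
        assert np.mean(dist.times) < 50
        # held OFF: module can never leave low -> all censored
        dist_ko = measure_switch_times(rs, start, ["A", "B", "C", "D"], {"S"},
                                       n_walks=20, n_steps=200, master_seed=1,
                                       held={"S": 0})
        assert dist_ko.times == [201] * 20

    def test_reproducible_under_master_seed(self):
        rs = RuleSet(rules={m: _rule(m, (m,), [0.4, 0.6]) for m in "ABCD"})
        start = dict.fromkeys("ABCD", 0)
        a = measure_switch_times(rs, start, list("ABCD"), set(), n_walks=10,
                                 n_steps=100, master_seed=3)
        b = measure_switch_times(rs, start, list("ABCD"), set(), n_walks=10,
                                 n_steps=100, master_seed=3)
        assert a.times == b.times


class TestCompareInterventions:
    def _dist(self, times, intervention="I", module="m1",
              direction="low->intermediate"):
        return SwitchTimeDistribution(
            module=module, direction=direction, times=list(times),
            intervention=intervention, condition="c1",
        )

    def test_identical_distributions_not_classified(self):
        wt = self._dist([100] * 50, intervention="WT")
        res = compare_interventions([wt], [self._dist([100] * 50)])
        assert res[0].p_raw == 1.0
        assert res[0].classification == "none"

    def test_extreme_slowdown_from_low_is_downregulating(self):
        wt = self._dist([100] * 100, intervention="WT")
        res = compare_interventions([wt], [self._dist([5001] * 100)])
        assert res[0].p_adjusted < 0.05
        assert res[0].classification == "downregulating"

    def test_extreme_speedup_from_low_is_upregulating(self):
        wt = self._dist([5001] * 100, intervention="WT")
        res = compare_interventions([wt], [self._dist([100] * 100)])
        assert res[0].classification == "upregulating"

    def test_intermediate_start_flips_mapping(self):
        wt = self._dist([100] * 100, intervention="WT",
                        direction="intermediate->low")
        res = compare_interventions(
            [wt], [self._dist([5001] * 100, direction="intermediate->low")]
        )
        assert res[0].classification == "upregulating"

    def test_bh_adjustment_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(0)
        wt = [self._dist(rng.integers(1, 5001, 30), intervention="WT",
                         module=f"m{i}") for i in range(6)]
        ints = [self._dist(rng.integers(1, 5001, 30), module=f"m{i}")
                for i in range(6)]
        res = compare_interventions(wt, ints)
        order = np.argsort([r.p_raw for r in res])
        adj = [res[i].p_adjusted for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(r.p_adjusted >= r.p_raw - 1e-12 for r in res)

    def test_mismatched_walk_counts_rejected(self):
        wt = self._dist([100] * 10, intervention="WT")
        with pytest.raises(ValueError):
            compare_interventions([wt], [self._dist([100] * 5)])
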