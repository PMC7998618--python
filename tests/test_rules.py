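"""Expression normalization, node splitting, activation solve, and
probabilistic rule inference with significance pruning."""

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbnet.rules import (
    ActivationEquation,
    NormalizedExpressionMatrix,
    build_activation_equations,
    classify_edge_types,
    infer_network_rules,
    infer_probabilistic_rule,
    normalize_expression,
    preprocess_expression,
    prune_insignificant_regulators,
    regulator_significance,
    solve_protein_activation,
    split_post_translational_nodes,
)


def _nem(frame, conditions=None):
    return NormalizedExpressionMatrix(
        values=frame,
        sample_conditions=conditions or {c: "all" for c in frame.columns},
        raw_transform="none",
    )


class TestPreprocess:
    def test_log1p_and_whitelist(self):
        raw = pd.DataFrame({"s1": [0.0, 10.0], "s2": [1.0, 3.0]}, index=["A", "B"])
        out = preprocess_expression(raw, {"A"})
        assert list(out.index) == ["A"]
        assert out.at["A", "s1"] == 0.0
        assert out.at["A", "s2"] == pytest.approx(np.log(2))

    def test_negative_rejected(self):
        raw = pd.DataFrame({"s1": [-1.0]}, index=["A"])
        with pytest.raises(ValueError):
            preprocess_expression(raw)

    def test_monotone(self):
        raw = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["A"])
        out = preprocess_expression(raw)
        assert out.at["A", "s1"] < out.at["A", "s2"]


class TestNormalize:
    def test_percentile_arithmetic(self):
        # 11 equally spaced points 0..10: p20 = 2, p80 = 8; value 5 -> 0.5
        frame = pd.DataFrame([np.arange(11.0)], index=["g"],
                             columns=[f"s{i}" for i in range(11)])
        out = normalize_expression(frame)
        v = out.values.loc["g"].to_numpy()
        assert v[5] == pytest.approx(0.5)
        assert v[0] == 0.0 and v[2] == 0.0  # at/below p20
        assert v[8] == 1.0 and v[10] == 1.0  # at/above p80
        assert v[3] == pytest.approx(1 / 6)

    def test_constant_gene_maps_to_half(self, caplog):
        frame = pd.DataFrame([[3.0, 3.0, 3.0]], index=["g"], columns=list("abc"))
        with caplog.at_level(logging.WARNING, logger="pbnet"):
            out = normalize_expression(frame)
        assert (out.values.loc["g"] == 0.5).all()
        assert any("0.5" in r.message for r in caplog.records)

    def test_extremes_map_to_zero_and_one(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.random((5, 12)),
                             columns=[f"s{i}" for i in range(12)])
        out = normalize_expression(frame)
        v = out.values.to_numpy()
        assert np.allclose(v.min(axis=1), 0.0)
        assert np.allclose(v.max(axis=1), 1.0)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            normalize_expression(pd.DataFrame({"s1": [1.0]}, index=["g"]))


class TestEdgeTypingAndSplitting:
    def _net(self):
        g = nx.DiGraph()
        g.add_edge("TF1", "X", sign="positive")
        g.add_edge("KIN", "X", sign="negative")
        g.add_edge("X", "Y")
        g.add_edge("TF1", "Y")
        return classify_edge_types(g, {"TF1"})

    def test_tf_source_is_transcriptional(self):
        g = self._net()
        assert g.edges["TF1", "X"]["regulation_type"] == "transcriptional"

    def test_non_tf_is_post_translational_with_sign(self):
        g = self._net()
        assert g.edges["KIN", "X"]["regulation_type"] == "post_translational"
        assert g.edges["KIN", "X"]["sign"] == "negative"
        # unannotated non-TF edge defaults to activating
        assert g.edges["X", "Y"]["regulation_type"] == "post_translational"
        assert g.edges["X", "Y"]["sign"] == "positive"

    def test_split_targets_and_sources(self):
        split = split_post_translational_nodes(self._net())
        # X is post-translationally regulated -> split; Y too (X->Y is PT)
        assert {"X_T", "X_A", "Y_T", "Y_A"} <= set(split.nodes)
        assert split.has_edge("TF1", "X_T")  # transcriptional in-edge to _T
        assert split.has_edge("KIN", "X_A")  # PT in-edge to _A
        assert split.has_edge("X_T", "X_A")
        assert split.has_edge("X_A", "Y_A")  # out-edges re-sourced to _A

    def test_purely_transcriptional_node_not_split(self):
        g = nx.DiGraph()
        g.add_edge("TF1", "Z")
        split = split_post_translational_nodes(classify_edge_types(g, {"TF1"}))
        assert "Z" in split.nodes and "Z_A" not in split.nodes

    def test_node_count_increases_by_split_count(self):
        g = self._net()
        split = split_post_translational_nodes(g)
        n_split = 2  # X and Y
        assert split.number_of_nodes() == g.number_of_nodes() + n_split


class TestActivationSolver:
    def test_single_activator(self):
        frame = pd.DataFrame({"s1": [0.8, 1.0]}, index=["X", "J"])
        eq = ActivationEquation("X", "X_T", ("J",), (), "X_A")
        out = solve_protein_activation(_nem(frame), [eq])
        assert out.values.at["X_A", "s1"] == pytest.approx(0.8)

    def test_no_activators_inhibitor_branch(self):
        frame = pd.DataFrame({"s1": [0.8, 0.25]}, index=["X", "M"])
        eq = ActivationEquation("X", "X_T", (), ("M",), "X_A")
        out = solve_protein_activation(_nem(frame), [eq])
        assert out.values.at["X_A", "s1"] == pytest.approx(0.6)

    def test_mutual_inhibition_converges_in_range(self):
        frame = pd.DataFrame({"s1": [1.0, 1.0]}, index=["X", "Y"])
        eqs = [
            ActivationEquation("X", "X_T", (), ("Y_A",), "X_A"),
            ActivationEquation("Y", "Y_T", (), ("X_A",), "Y_A"),
        ]
        out = solve_protein_activation(_nem(frame), eqs, tol=1e-10)
        xa = out.values.at["X_A", "s1"]
        ya = out.values.at["Y_A", "s1"]
        assert 0 <= xa <= 1 and 0 <= ya <= 1
        # residuals of both equations below tolerance
        assert abs(xa - 1.0 * max(1 - ya, 0)) < 1e-8
        assert abs(ya - 1.0 * max(1 - xa, 0)) < 1e-8

    def test_inhibitor_monotonicity(self):
        values = []
        for m in (0.0, 0.3, 0.7, 1.0):
            frame = pd.DataFrame({"s1": [0.9, 1.0, m]}, index=["X", "J", "M"])
            eq = ActivationEquation("X", "X_T", ("J",), ("M",), "X_A")
            out = solve_protein_activation(_nem(frame), [eq])
            values.append(out.values.at["X_A", "s1"])
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            solve_protein_activation(
                _nem(pd.DataFrame({"s1": [1.0]}, index=["X"])), [], tol=0
            )


class TestRuleInference:
    def test_unsupported_configuration_is_exactly_half(self):
        # regulator always ON: the reg=0 configuration has zero support
        frame = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [1.0, 1.0]}, index=["R", "T"]
        )
        rule = infer_probabilistic_rule("T", ("R",), _nem(frame))
        assert rule.support[0] == 0.0
        assert rule.table[0] == 0.5

    def test_many_identical_samples_converge(self):
        # 100 samples exactly at configuration reg=1 with target 1
        frame = pd.DataFrame(
            np.ones((2, 100)), index=["R", "T"],
            columns=[f"s{i}" for i in range(100)],
        )
        rule = infer_probabilistic_rule("T", ("R",), _nem(frame))
        assert rule.table[1] == pytest.approx(100.5 / 101)

    def test_identity_rule_recovery(self):
        frame = pd.DataFrame(
            {"s1": [0.0, 0.0], "s2": [1.0, 1.0]}, index=["R", "T"]
        )
        rule = infer_probabilistic_rule("T", ("R",), _nem(frame))
        assert (rule.table >= 0.5).astype(int).tolist() == [0, 1]

    def test_zero_regulators_is_source_prior(self):
        frame = pd.DataFrame({"s1": [0.3], "s2": [0.9]}, index=["T"])
        rule = infer_probabilistic_rule("T", (), _nem(frame))
        assert rule.table.tolist() == [0.5]

    def test_many_regulators_warn(self):
        rng = np.random.default_rng(1)
        genes = [f"R{i}" for i in range(7)] + ["T"]
        frame = pd.DataFrame(rng.random((8, 4)), index=genes,
                             columns=list("abcd"))
        with pytest.warns(UserWarning, match="regulators"):
            infer_probabilistic_rule("T", tuple(genes[:7]), _nem(frame))

    @given(st.integers(0, 3), st.integers(0, 100))
    @settings(deadline=None, max_examples=40)
    def test_adding_positive_sample_never_decreases(self, cfg, seed):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(rng.random((3, 6)), index=["A", "B", "T"],
                             columns=[f"s{i}" for i in range(6)])
        base = infer_probabilistic_rule("T", ("A", "B"), _nem(frame))
        bits = [(cfg >> 1) & 1, cfg & 1]
        extra = pd.DataFrame({"new": [float(bits[0]), float(bits[1]), 1.0]},
                             index=["A", "B", "T"])
        grown = infer_probabilistic_rule(
            "T", ("A", "B"), _nem(pd.concat([frame, extra], axis=1))
        )
        assert grown.table[cfg] >= base.table[cfg] - 1e-12

    def test_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.random((4, 10)), index=["A", "B", "C", "T"],
                             columns=[f"s{i}" for i in range(10)])
        rule = infer_probabilistic_rule("T", ("A", "B", "C"), _nem(frame))
        assert (rule.table >= 0).all() and (rule.table <= 1).all()


class TestSignificance:
    def test_ignored_regulator_scores_zero(self):
        from pbnet.rules import ProbabilisticRule

        rule = ProbabilisticRule("T", ("A", "B"), [0.2, 0.2, 0.9, 0.9], np.ones(4))
        assert regulator_significance(rule, "B").value == 0.0
        assert regulator_significance(rule, "A").value == pytest.approx(0.7)

    def test_identity_rule_scores_one(self):
        from pbnet.rules import ProbabilisticRule

        rule = ProbabilisticRule("T", ("A",), [0.0, 1.0], np.ones(2))
        assert regulator_significance(rule, "A").value == 1.0

    def test_or_and_rule_significance(self, worked_rule):
        # in context B=C=0, flipping A moves the output 0 -> 1
        assert regulator_significance(worked_rule, "A").value == 1.0
        assert regulator_significance(worked_rule, "B").value == 1.0


class TestPruning:
    def test_spurious_regulator_removed(self):
        # T copies R1; R2 is noise uncorrelated with T
        frame = pd.DataFrame(
            {
                "s1": [0.0, 0.0, 0.0], "s2": [0.0, 1.0, 0.0],
                "s3": [1.0, 0.0, 1.0], "s4": [1.0, 1.0, 1.0],
            },
            index=["R1", "R2", "T"],
        )
        rule = prune_insignificant_regulators("T", ["R1", "R2"], _nem(frame))
        assert rule.regulators == ("R1",)

    def test_all_spurious_yields_source(self):
        frame = pd.DataFrame(
            {"s1": [0.0, 0.5], "s2": [1.0, 0.5]}, index=["R", "T"]
        )
        rule = prune_insignificant_regulators("T", ["R"], _nem(frame))
        assert rule.regulators == ()
        assert rule.table.tolist() == [0.5]

    def test_terminates_within_n_iterations(self):
        rng = np.random.default_rng(5)
        genes = ["R1", "R2", "R3", "R4", "T"]
        frame = pd.DataFrame(0.5 + 0.001 * rng.random((5, 8)), index=genes,
                             columns=[f"s{i}" for i in range(8)])
        rule = prune_insignificant_regulators("T", genes[:4], _nem(frame))
        assert rule.regulators == ()  # near-constant data: everything pruned

    def test_bad_threshold_rejected(self):
        frame = pd.DataFrame({"s1": [0.0, 0.0]}, index=["R", "T"])
        with pytest.raises(ValueError):
            prune_insignificant_regulators("T", ["R"], _nem(frame), threshold=1.5)


def test_infer_network_rules_end_to_end():
    """Whole-network inference on a small mixed TF/kinase system produces a
    rule or source flag for every split node."""
    g = nx.DiGraph()
    g.add_edge("TF1", "X")
    g.add_edge("KIN", "X", sign="negative")
    g.add_edge("X", "TF1")
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(rng.random((3, 12)), index=["TF1", "KIN", "X"],
                         columns=[f"s{i}" for i in range(12)])
    normalized = _nem(frame)
    ruleset, split, training = infer_network_rules(g, normalized, {"TF1"})
    covered = set(ruleset.rules) | ruleset.source_nodes
    assert covered == set(split.nodes)
    assert "X_A" in ruleset.rules and ruleset.rules["X_A"].deterministic
    assert "X_A" in training.values.index
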