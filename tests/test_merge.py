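"""Rule-composition strategies and whole-model merging."""

import pytest

from boolmerge import (
    LogicalModel,
    MergeConfig,
    SynthParams,
    attractors,
    combine_and,
    combine_iw,
    combine_or,
    exprs_equivalent,
    merge_models,
    overlapping_pair,
    parse_rule,
)
from boolmerge.merge import MergeConfigError

from oracles import all_states, oracle_and, oracle_iw, oracle_or, oracle_vars


def _rules(*texts):
    return [parse_rule(t) for t in texts]


class TestCombiners:
    def test_or_unary_identity(self):
        assert exprs_equivalent(combine_or(_rules("A")), parse_rule("A"))

    @pytest.mark.parametrize(
        "texts", [("A", "!B"), ("A", "A & B"), ("A & !C", "B"), ("A", "B", "!C")]
    )
    def test_or_matches_pointwise_max(self, texts):
        rules = _rules(*texts)
        combined = combine_or(rules)
        names = sorted(set().union(*(oracle_vars(r) for r in rules)))
        for state in all_states(names):
            assert combined(state) == oracle_or(rules, state)

    def test_and_contradiction_is_constant_zero(self):
        combined = combine_and(_rules("A", "!A"))
        for state in all_states(["A"]):
            assert combined(state) == 0

    @pytest.mark.parametrize(
        "texts", [("A", "!B"), ("A",), ("A & B", "A | C")]
    )
    def test_and_matches_pointwise_min(self, texts):
        rules = _rules(*texts)
        combined = combine_and(rules)
        names = sorted(set().union(*(oracle_vars(r) for r in rules)))
        for state in all_states(names):
            assert combined(state) == oracle_and(rules, state)

    def test_iw_inhibitor_dominates(self):
        # sources "A" and "!B": B is an inhibitor, so the result is 0
        # whenever B is on and A | !B (== 1) otherwise: exactly "!B"
        combined = combine_iw(_rules("A", "!B"))
        assert exprs_equivalent(combined, parse_rule("!B"))

    def test_iw_without_inhibitors_equals_or(self):
        rules = _rules("A", "B")
        assert exprs_equivalent(combine_iw(rules), combine_or(rules))

    @pytest.mark.parametrize(
        "texts",
        [("A", "!B"), ("A & !C", "B"), ("A | !B", "C & !D"), ("A", "B")],
    )
    def test_iw_matches_piecewise_definition(self, texts):
        rules = _rules(*texts)
        combined = combine_iw(rules)
        names = sorted(set().union(*(oracle_vars(r) for r in rules)))
        for state in all_states(names):
            assert combined(state) == oracle_iw(rules, state)

    def test_dual_regulator_warns_and_inhibits(self):
        rules = _rules("A & !B | !A & B", "C")
        with pytest.warns(UserWarning, match="dual"):
            combined = combine_iw(rules)
        # both A and B pooled as inhibitors: result 0 whenever either is on
        assert combined({"A": 1, "B": 0, "C": 1}) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_pointwise_bounds_against_or(self, seed):
        # AND and IW never exceed OR on any state (IW additionally zeroes
        # the states where a pooled inhibitor is active, so it is not in
        # general above AND: a source rule may be ON despite an active
        # inhibitor of another source rule)
        a, b, shared = overlapping_pair(
            SynthParams(n_nodes=7, k_regulators=3, seed=seed, overlap=3,
                        divergence=1.0, activation_bias=0.5)
        )
        for sym in shared:
            rules = [
                m[sym].rule for m in (a, b) if m[sym].rule is not None
            ]
            if not rules:
                continue
            lo, mid, hi = (
                combine_and(rules), combine_iw(rules), combine_or(rules)
            )
            names = sorted(set().union(*(oracle_vars(r) for r in rules)))
            for state in all_states(names):
                assert lo(state) <= hi(state)
                assert mid(state) <= hi(state)

    def test_ordering_chain_holds_on_template_form_rules(self):
        # for rules in activator/inhibitor template form a rule cannot be
        # ON while one of its inhibitors is active, so AND <= IW <= OR
        rules = _rules("A & !B", "(A | C) & !D")
        lo, mid, hi = (
            combine_and(rules), combine_iw(rules), combine_or(rules)
        )
        for state in all_states(["A", "B", "C", "D"]):
            assert lo(state) <= mid(state) <= hi(state)


class TestMergeModels:
    def test_disjoint_union(self):
        a = LogicalModel.from_rules({"A": None, "B": "A"}, model_id="a")
        b = LogicalModel.from_rules({"C": None, "D": "!C"}, model_id="b")
        merged, report = merge_models([a, b])
        assert set(merged.nodes) == {"A", "B", "C", "D"}
        assert merged.rules_text() == {**a.rules_text(), **b.rules_text()}
        assert set(report["strategy"]) <= {"single", "input"}

    @pytest.mark.parametrize("strategy", ["OR", "AND"])
    def test_self_merge_preserves_rules_and_fixed_points(self, strategy):
        m = LogicalModel.from_rules(
            {"A": None, "B": "A & !C", "C": "B | C"}, model_id="m"
        )
        merged, _ = merge_models(
            [m, m.copy("m2")], MergeConfig(strategy)
        )
        for nid, node in m.nodes.items():
            if node.rule is None:
                assert merged[nid].rule is None
            else:
                assert exprs_equivalent(merged[nid].rule, node.rule)
        fp = lambda mod: {
            tuple(sorted(a.states[0].items()))
            for a in attractors(mod, scheme="synchronous")
            if a.is_fixed_point
        }
        assert fp(m) == fp(merged)

    def test_input_vs_regulated_resolves_to_regulated(self):
        a = LogicalModel.from_rules({"X": None, "Y": "X"}, model_id="a")
        b = LogicalModel.from_rules({"X": "Y", "Y": None}, model_id="b")
        merged, report = merge_models([a, b], MergeConfig("AND"))
        assert merged["X"].rule is not None and merged["Y"].rule is not None
        assert exprs_equivalent(merged["X"].rule, parse_rule("Y"))
        rep = report.set_index("node")
        assert rep.loc["X", "strategy"] == "single"

    def test_order_invariance(self):
        a, b, shared = overlapping_pair(
            SynthParams(n_nodes=6, seed=3, overlap=2, divergence=1.0,
                        activation_bias=0.5, k_regulators=2)
        )
        for strategy in ("OR", "AND", "IW"):
            m1, _ = merge_models([a, b], MergeConfig(strategy))
            m2, _ = merge_models([b, a], MergeConfig(strategy))
            for nid in m1.nodes:
                r1, r2 = m1[nid].rule, m2[nid].rule
                assert (r1 is None) == (r2 is None)
                if r1 is not None:
                    assert exprs_equivalent(r1, r2), nid

    def test_per_node_override_and_report(self):
        a = LogicalModel.from_rules({"T": "A", "A": None}, model_id="a")
        b = LogicalModel.from_rules({"T": "!B", "B": None}, model_id="b")
        merged, report = merge_models(
            [a, b], MergeConfig("OR", per_node={"T": "IW"})
        )
        assert exprs_equivalent(merged["T"].rule, parse_rule("!B"))
        rep = report.set_index("node")
        assert rep.loc["T", "strategy"] == "IW"
        assert rep.loc["T", "inhibitors_used"] == "B"
        assert rep.loc["T", "sources"] == "a;b"

    def test_unknown_per_node_key_rejected(self):
        a = LogicalModel.from_rules({"A": None}, model_id="a")
        b = LogicalModel.from_rules({"A": "A | A"}, model_id="b")
        with pytest.raises(MergeConfigError, match="ZZZ"):
            merge_models([a, b], MergeConfig("OR", per_node={"ZZZ": "IW"}))

    def test_three_way_merge(self):
        ms = [
            LogicalModel.from_rules({"T": t, "A": None, "B": None, "C": None},
                                    model_id=f"m{i}")
            for i, t in enumerate(["A", "B", "!C"])
        ]
        merged, _ = merge_models(ms, MergeConfig("OR"))
        assert exprs_equivalent(merged["T"].rule, parse_rule("A | B | !C"))

    def test_annotations_pooled(self):
        a = LogicalModel.from_rules({"G": None}, model_id="a")
        b = LogicalModel.from_rules({"G": None}, model_id="b")
        a["G"].annotations["bqbiol:is"] = ["u1"]
        b["G"].annotations["bqbiol:is"] = ["u1", "u2"]
        merged, _ = merge_models([a, b])
        assert merged["G"].annotations["bqbiol:is"] == ["u1", "u2"]
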