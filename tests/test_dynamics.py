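"""Update schemes, attractor detection, activation frequency, clamping."""

import pytest

from boolmerge import (
    LogicalModel,
    MutationProfile,
    SynthParams,
    activation_frequency,
    async_successors,
    attractors,
    attractors_to_frame,
    clamp,
    random_model,
    sync_step,
)
from boolmerge.dynamics import (
    ASYNC,
    SYNC,
    StateSpaceCapError,
    decode_state,
    encode_state,
)

from oracles import oracle_async_attractors, oracle_sync_attractors


def _as_keysets(attrs):
    return {
        frozenset(tuple(sorted(s.items())) for s in a.states) for a in attrs
    }


class TestStepping:
    def test_sync_fixed_point(self):
        m = LogicalModel.from_rules({"A": "A"})
        assert sync_step(m, {"A": 1}) == {"A": 1}

    def test_sync_swap(self, mutual_activation):
        assert sync_step(mutual_activation, {"A": 0, "B": 1}) == {
            "A": 1, "B": 0,
        }

    def test_sync_composition(self, toy_regulon):
        # stepping twice equals composing the map with itself
        state = {"IN": 1, "X": 0, "Y": 0, "Z": 0}
        one = sync_step(toy_regulon, state)
        two = sync_step(toy_regulon, one)
        assert two == sync_step(toy_regulon, sync_step(toy_regulon, state))

    def test_inputs_held(self, toy_regulon):
        state = {"IN": 1, "X": 1, "Y": 1, "Z": 0}
        assert sync_step(toy_regulon, state)["IN"] == 1

    def test_async_fixed_point_has_no_successors(self):
        m = LogicalModel.from_rules({"A": "A | A"})
        assert async_successors(m, {"A": 1}) == []

    def test_async_two_unstable_nodes(self, mutual_activation):
        succs = async_successors(mutual_activation, {"A": 0, "B": 1})
        assert sorted(tuple(sorted(s.items())) for s in succs) == [
            (("A", 0), ("B", 0)),
            (("A", 1), ("B", 1)),
        ]

    def test_async_stability_census(self, mutual_activation):
        counts = {
            (a, b): len(async_successors(mutual_activation, {"A": a, "B": b}))
            for a in (0, 1) for b in (0, 1)
        }
        assert counts == {(0, 0): 0, (1, 1): 0, (0, 1): 2, (1, 0): 2}


class TestEncoding:
    def test_encode_decode_bijection(self):
        order = ["A", "B", "C"]
        for code in range(8):
            assert encode_state(decode_state(code, order), order) == code


class TestAttractorsMicro:
    def test_sync_mutual_activation(self, mutual_activation):
        attrs = attractors(mutual_activation, scheme=SYNC)
        kinds = sorted((a.kind, len(a)) for a in attrs)
        assert kinds == [("cyclic", 2), ("fixed_point", 1), ("fixed_point", 1)]
        assert _as_keysets(attrs) == {
            frozenset({(("A", 0), ("B", 0))}),
            frozenset({(("A", 1), ("B", 1))}),
            frozenset({(("A", 0), ("B", 1)), (("A", 1), ("B", 0))}),
        }

    def test_async_mutual_activation_drops_cycle(self, mutual_activation):
        attrs = attractors(mutual_activation, scheme=ASYNC)
        assert all(a.is_fixed_point for a in attrs)
        assert _as_keysets(attrs) == {
            frozenset({(("A", 0), ("B", 0))}),
            frozenset({(("A", 1), ("B", 1))}),
        }

    def test_async_negative_loop_is_one_four_state_cycle(self, negative_loop):
        (attr,) = attractors(negative_loop, scheme=ASYNC)
        assert attr.kind == "cyclic" and len(attr) == 4

    def test_canonical_order_and_labels(self, mutual_activation):
        attrs = attractors(mutual_activation, scheme=SYNC, label_prefix="M")
        assert [a.label for a in attrs] == ["M1", "M2", "M3"]
        order = sorted(mutual_activation.nodes)
        firsts = [encode_state(a.states[0], order) for a in attrs]
        assert firsts == sorted(firsts)

    def test_input_contexts_enumerated(self, toy_regulon):
        attrs = attractors(toy_regulon, scheme=ASYNC)
        assert {a.input_context["IN"] for a in attrs} == {0, 1}


class TestAttractorsProperties:
    @pytest.mark.parametrize("seed", range(15))
    def test_fixed_points_agree_across_schemes(self, seed):
        m = random_model(SynthParams(n_nodes=7, k_regulators=3, seed=seed,
                                     activation_bias=0.5))
        fp_sync = {
            tuple(sorted(a.states[0].items()))
            for a in attractors(m, scheme=SYNC) if a.is_fixed_point
        }
        fp_async = {
            tuple(sorted(a.states[0].items()))
            for a in attractors(m, scheme=ASYNC) if a.is_fixed_point
        }
        assert fp_sync == fp_async

    @pytest.mark.parametrize("seed", range(10))
    def test_sync_matches_map_iteration_oracle(self, seed):
        m = random_model(SynthParams(n_nodes=6, k_regulators=3, seed=seed,
                                     activation_bias=0.5))
        rules = {nid: n.rule for nid, n in m.nodes.items()}
        assert _as_keysets(attractors(m, scheme=SYNC)) == (
            oracle_sync_attractors(rules)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_async_matches_terminal_scc_oracle(self, seed):
        m = random_model(SynthParams(n_nodes=6, k_regulators=3, seed=seed,
                                     activation_bias=0.5))
        rules = {nid: n.rule for nid, n in m.nodes.items()}
        assert _as_keysets(attractors(m, scheme=ASYNC)) == (
            oracle_async_attractors(rules)
        )

    def test_sync_basins_partition_state_space(self, negative_loop):
        # every state reaches exactly one attractor; total census = 2^n
        attrs = attractors(negative_loop, scheme=SYNC)
        assert sum(len(a) for a in attrs) <= 4
        # the deterministic map assigns each of the 4 states a unique orbit
        seen = set()
        for a in attrs:
            for s in a.states:
                key = tuple(sorted(s.items()))
                assert key not in seen
                seen.add(key)

    def test_cap_error_and_sampling_fallback(self):
        m = random_model(SynthParams(n_nodes=10, k_regulators=2, seed=1))
        with pytest.raises(StateSpaceCapError):
            attractors(m, scheme=SYNC, cap=8)
        sampled = attractors(m, scheme=SYNC, cap=8, mode="sample",
                             n_samples=100, seed=0)
        assert sampled and all(not a.complete for a in sampled)
        exact = attractors(m, scheme=SYNC)
        assert _as_keysets(sampled) <= _as_keysets(exact)

    def test_async_sampling_finds_only_true_attractors(self):
        m = random_model(SynthParams(n_nodes=8, k_regulators=3, seed=7,
                                     activation_bias=0.5))
        sampled = attractors(m, scheme=ASYNC, mode="sample", n_samples=60,
                             seed=0)
        exact = attractors(m, scheme=ASYNC)
        assert _as_keysets(sampled) <= _as_keysets(exact)


class TestActivationFrequency:
    def test_uniform_attractor_hand_value(self, mutual_activation):
        attrs = attractors(mutual_activation, scheme=SYNC)
        freq = activation_frequency(attrs, weighting="uniform_attractor")
        assert freq["A"] == pytest.approx((0 + 1 + 0.5) / 3)

    def test_uniform_state_hand_value(self, mutual_activation):
        attrs = attractors(mutual_activation, scheme=SYNC)
        freq = activation_frequency(attrs, weighting="uniform_state")
        assert freq["A"] == pytest.approx(0.5)

    def test_single_fixed_point_gives_its_bits(self):
        m = LogicalModel.from_rules({"A": "1", "B": "!A"})
        (attr,) = attractors(m, scheme=ASYNC)
        freq = activation_frequency([attr])
        assert freq == {"A": 1.0, "B": 0.0}

    def test_bounds(self, negative_loop):
        freq = activation_frequency(attractors(negative_loop, scheme=ASYNC))
        assert all(0.0 <= v <= 1.0 for v in freq.values())


class TestClamp:
    def test_lof_forces_unique_off_attractor(self, mutual_activation):
        clamped = clamp(mutual_activation, MutationProfile({"A": "LoF"}))
        attrs = attractors(clamped, scheme=ASYNC)
        assert _as_keysets(attrs) == {frozenset({(("A", 0), ("B", 0))})}

    def test_empty_profile_is_identity(self, toy_regulon):
        clamped = clamp(toy_regulon, MutationProfile({}))
        assert clamped.rules_text() == toy_regulon.rules_text()

    def test_gof_gene_on_in_every_attractor(self, toy_regulon):
        clamped = clamp(toy_regulon, MutationProfile({"Y": "GoF"}))
        for a in attractors(clamped, scheme=ASYNC):
            assert all(s["Y"] == 1 for s in a.states)
        freq = activation_frequency(attractors(clamped, scheme=ASYNC))
        assert freq["Y"] == 1.0

    def test_unknown_gene_listed(self, toy_regulon):
        with pytest.raises(KeyError, match="NOPE"):
            clamp(toy_regulon, MutationProfile({"NOPE": "LoF"}))


class TestFrame:
    def test_one_row_per_state_with_labels(self, mutual_activation):
        frame = attractors_to_frame(
            attractors(mutual_activation, scheme=SYNC, label_prefix="M")
        )
        assert len(frame) == 4  # 1 + 1 + 2 states
        assert set(frame["label"]) == {"M1", "M2", "M3"}
        assert list(frame.columns[:5]) == [
            "label", "state", "kind", "scheme", "complete",
        ]
        assert {"A", "B"} <= set(frame.columns)
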