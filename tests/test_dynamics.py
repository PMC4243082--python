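"""Successor relations, stable-state enumeration, attractor detection."""

import itertools

import pytest

from logicfate import (
    Atom,
    Component,
    LogicalModel,
    Not,
    Rule,
    StateSpaceTooLarge,
    attractors,
    brute_force_stable_states,
    stable_states,
    successors,
)
from logicfate.g1s import _RULES  # reduced-core fixture reuses the same rules
from logicfate.io import parse_condition
from logicfate.synthetic import RandomModelSpec, random_model


def toggle_switch():
    """Mutual inhibition: two stable states (1,0) and (0,1)."""
    comps = [Component("A", 1), Component("B", 1)]
    rules = [
        Rule("A", 1, Not(Atom("B", 1, 1))),
        Rule("B", 1, Not(Atom("A", 1, 1))),
    ]
    return LogicalModel(comps, rules, name="toggle")


def negative_loop():
    """One component repressing itself: a forced 2-cycle, no fixed point."""
    comps = [Component("A", 1)]
    rules = [Rule("A", 1, Not(Atom("A", 1, 1)))]
    return LogicalModel(comps, rules, name="negloop")


@pytest.fixture(scope="module")
def g1s_core():
    """The cyclic core of the G1/S network with its upstream fixed as inputs.

    Small enough (384 states per input combination) for exhaustive
    cross-checks of the decomposition-based enumeration.
    """
    inputs = {"p38MAPK": 3, "ATM": 2, "ATR": 2, "CHEK1": 1, "CHEK2": 1,
              "CDC25A": 2, "p16INK4a": 2}
    internals = ("p14ARF", "Mdm2", "p53", "p21", "E2F", "RB1",
                 "CDK46CycD", "CDK2CycE")
    comps = [Component(n, m, "input") for n, m in inputs.items()]
    comps += [Component(n, 2 if n == "p53" else 1) for n in internals]
    max_levels = {c.name: c.max_level for c in comps}
    rules = [
        Rule(c, t, parse_condition(expr, max_levels))
        for c, t, expr in _RULES
        if c in internals
    ]
    model = LogicalModel(comps, rules, name="g1s-core")
    assert model.validate() == []
    return model


class TestSuccessors:
    def test_stable_state_has_no_successors(self, g1s, wt_states):
        for state in wt_states.values():
            assert successors(g1s, state, "asynchronous") == set()
            assert successors(g1s, state, "synchronous") == set()

    def test_unit_step_toward_image_not_jump(self, g1s, wt_states):
        state = dict(wt_states[(0, 0)], DSB=2)  # sudden irreparable DSB
        succ = successors(g1s, state, "asynchronous")
        raised_atm = dict(state, ATM=1)
        assert tuple(sorted(raised_atm.items())) in {
            tuple(sorted(s)) for s in succ
        }
        assert all(dict(s)["ATM"] != 2 for s in succ)

    def test_async_successor_count_equals_enabled_components(self, g1s, wt_states):
        state = dict(wt_states[(0, 0)], DSB=2)
        image = g1s.image_vector(state)
        enabled = sum(1 for n in g1s.names if image[n] != state[n])
        assert len(successors(g1s, state, "asynchronous")) == enabled
        assert len(successors(g1s, state, "synchronous")) == 1


class TestStableStates:
    def test_g1s_unique_stable_state_per_condition(self, g1s):
        total = []
        for ssb, dsb in itertools.product(range(3), range(3)):
            found = stable_states(g1s, {"SSB": ssb, "DSB": dsb})
            assert len(found) == 1
            total.extend(found)
        assert len(total) == 9

    def test_decomposition_matches_bruteforce_on_g1s_core(self, g1s_core):
        for combo in [(3, 2, 2, 1, 1, 2, 2), (0, 0, 0, 0, 0, 2, 0),
                      (1, 1, 0, 0, 0, 1, 1), (2, 2, 0, 1, 0, 0, 2)]:
            assignment = dict(zip(g1s_core.inputs, combo))
            assert stable_states(g1s_core, assignment) == \
                brute_force_stable_states(g1s_core, assignment)

    def test_decomposition_matches_bruteforce_on_random_models(self):
        for seed in range(60):
            model = random_model(RandomModelSpec(
                n_components=6, max_level_choices=(1, 2), n_inputs=1,
                edge_density=0.5, seed=seed,
            ))
            for lvl in range(model.max_level(model.inputs[0]) + 1):
                assignment = {model.inputs[0]: lvl}
                assert stable_states(model, assignment) == \
                    brute_force_stable_states(model, assignment), seed

    def test_stable_states_scheme_independent(self):
        """Fixed points coincide with successor-free states of both schemes."""
        for seed in range(25):
            model = random_model(RandomModelSpec(
                n_components=5, max_level_choices=(1, 2), n_inputs=1,
                edge_density=0.6, seed=seed,
            ))
            inp = model.inputs[0]
            for lvl in range(model.max_level(inp) + 1):
                fixed = {
                    tuple(sorted(s.items()))
                    for s in stable_states(model, {inp: lvl})
                }
                comp = model.compiled
                space = itertools.product(
                    *(range(model.max_level(n) + 1) if n != inp else (lvl,)
                      for n in model.names)
                )
                for levels in space:
                    state = dict(zip(model.names, levels))
                    empty_async = not successors(model, state, "asynchronous")
                    empty_sync = not successors(model, state, "synchronous")
                    assert empty_async == empty_sync
                    assert empty_async == (tuple(sorted(state.items())) in fixed)

    def test_input_only_model_has_single_trivial_stable_state(self):
        model = LogicalModel([Component("I", 2, "input")], [])
        assert stable_states(model, {"I": 1}) == [{"I": 1}]

    def test_clamped_input_equivalent_to_fixing_level(self, g1s):
        clamped = g1s.with_clamps({"DSB": (2, 2)})
        for ssb in range(3):
            # whatever DSB level is requested, the clamp pins it at 2
            a = stable_states(clamped, {"SSB": ssb, "DSB": 0})
            b = stable_states(g1s, {"SSB": ssb, "DSB": 2})
            for s in a:
                s_free = dict(s)
                assert s_free["DSB"] == 2
            assert [{k: v for k, v in s.items()} for s in a] == b

    def test_bruteforce_refuses_oversized_spaces(self, g1s):
        with pytest.raises(StateSpaceTooLarge):
            brute_force_stable_states(g1s, {"SSB": 0, "DSB": 0}, cap=1000)


class TestAttractors:
    def test_toggle_switch_has_two_stable_attractors(self):
        model = toggle_switch()
        found = attractors(model, {})
        assert len(found) == 2
        assert all(a.kind == "stable_state" for a in found)

    def test_negative_self_loop_forces_a_two_state_cycle(self):
        model = negative_loop()
        found = attractors(model, {}, scheme="asynchronous")
        assert len(found) == 1
        assert found[0].kind == "complex"
        assert len(found[0]) == 2

    def test_g1s_core_has_single_stable_attractor_under_full_damage(self, g1s_core):
        assignment = dict(zip(g1s_core.inputs, (3, 2, 2, 1, 1, 0, 2)))
        found = attractors(g1s_core, assignment)
        assert [a.kind for a in found] == ["stable_state"]

    def test_attractor_states_are_closed_and_strongly_connected(self):
        model = negative_loop()
        (attractor,) = attractors(model, {})
        member_keys = {tuple(sorted(s)) for s in attractor.states}
        for s in attractor.states:
            succ = successors(model, dict(s), "asynchronous")
            assert succ, "complex attractor states must have successors"
            assert {tuple(sorted(x)) for x in succ} <= member_keys

    def test_cap_refusal_mentions_initial_states_escape_hatch(self, g1s):
        with pytest.raises(StateSpaceTooLarge, match="initial_states"):
            attractors(g1s, {"SSB": 0, "DSB": 0}, cap=10_000)

    def test_reachable_exploration_from_initial_states(self, g1s, wt_states):
        start = dict(wt_states[(0, 0)])
        found = attractors(
            g1s, {"SSB": 2, "DSB": 2}, initial_states=[start], cap=200_000
        )
        assert len(found) == 1
        assert found[0].kind == "stable_state"
        (state,) = found[0].as_dicts()
        assert state == wt_states[(2, 2)]
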