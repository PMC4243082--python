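"""Circuit enumeration, signs, and functionality-context analysis."""

import itertools
import random

import networkx as nx
import pytest

from logicfate import (
    apply_perturbation,
    circuit_functionality,
    edge_decisive_contexts,
    enumerate_circuits,
    gain_of_function,
    stable_states,
)
from logicfate.circuits import _canonical_rotation
from logicfate.synthetic import RandomModelSpec, random_model


def brute_force_simple_cycles(graph):
    """Independent simple-cycle enumeration by restricted DFS.

    For each start node (in sorted order) only nodes sorting after it may
    appear on the path, so every cycle is produced exactly once, rooted at
    its smallest node.
    """
    cycles = []

    def extend(start, node, path, on_path):
        for nxt in graph.successors(node):
            if nxt == start:
                cycles.append(tuple(path))
            elif nxt > start and nxt not in on_path:
                extend(start, nxt, path + [nxt], on_path | {nxt})

    for start in sorted(graph.nodes):
        extend(start, start, [start], {start})
    return sorted(cycles)


@pytest.fixture(scope="module")
def g1s_circuits(g1s_graph):
    return enumerate_circuits(g1s_graph)


class TestEnumeration:
    def test_g1s_has_four_simple_circuits(self, g1s_circuits):
        assert len(g1s_circuits) == 4

    def test_exactly_one_positive_circuit(self, g1s_circuits):
        positive = [c for c in g1s_circuits if c.sign == "+"]
        assert len(positive) == 1
        assert set(positive[0].nodes) == {"CDK2CycE", "RB1", "E2F"}

    def test_p53_mdm2_circuit_is_negative(self, g1s_circuits):
        (loop,) = [c for c in g1s_circuits if set(c.nodes) == {"p53", "Mdm2"}]
        assert loop.sign == "-"
        assert sorted(loop.edge_signs) == ["+", "-"]

    def test_long_negative_circuits_through_the_cyclin_axis(self, g1s_circuits):
        long = [c for c in g1s_circuits if len(c.nodes) == 7]
        assert len(long) == 2
        for c in long:
            assert c.sign == "-"
            assert {"E2F", "p14ARF", "Mdm2", "p53", "p21", "RB1"} < set(c.nodes)
        cyclins = {frozenset(set(c.nodes) - {"E2F", "p14ARF", "Mdm2", "p53",
                                             "p21", "RB1"}) for c in long}
        assert cyclins == {frozenset({"CDK2CycE"}), frozenset({"CDK46CycD"})}

    def test_sign_is_parity_of_inhibitions(self, g1s_circuits):
        for c in g1s_circuits:
            expected = "+" if c.edge_signs.count("-") % 2 == 0 else "-"
            assert c.sign == expected

    def test_matches_bruteforce_on_random_graphs(self):
        rng = random.Random(7)
        for trial in range(30):
            n = rng.randint(3, 8)
            g = nx.DiGraph()
            g.add_nodes_from(f"n{i}" for i in range(n))
            for u, v in itertools.product(list(g.nodes), repeat=2):
                if rng.random() < 0.25:
                    g.add_edge(u, v, sign=rng.choice("+-"))
            found = {c.nodes for c in enumerate_circuits(g)}
            expected = {_canonical_rotation(c) for c in brute_force_simple_cycles(g)}
            assert found == expected, trial


class TestEdgeDecisiveness:
    def test_single_regulator_edge_always_decisive(self, g1s):
        contexts = edge_decisive_contexts(g1s, ("RB1", "E2F"))
        assert contexts[(1, 1)] == [{}]

    def test_mdm2_to_p53_needs_the_damage_signal(self, g1s):
        contexts = edge_decisive_contexts(g1s, ("Mdm2", "p53"))
        # decisive only between p53 levels 1 and 2, and only when the
        # upstream damage-signal disjunction holds
        assert contexts[(1, 1)] == []
        signal_regs = ("p38MAPK", "ATR", "ATM", "CHEK1", "CHEK2")
        for ctx in contexts[(1, 2)]:
            assert ctx["p38MAPK"] == 3 or any(ctx[r] >= 1 for r in signal_regs[1:])
        assert contexts[(1, 2)], "signal contexts must exist"

    def test_p16_to_cdk46_decisive_context(self, g1s):
        contexts = edge_decisive_contexts(g1s, ("p16INK4a", "CDK46CycD"))
        assert contexts[(1, 1)] == [
            {"CDC25A": 1, "p21": 0},
            {"CDC25A": 2, "p21": 0},
        ]
        assert contexts[(2, 1)] == []


class TestFunctionality:
    def test_positive_circuit_not_sustainable_in_wild_type(self, g1s, g1s_circuits):
        (pos,) = [c for c in g1s_circuits if c.sign == "+"]
        report = circuit_functionality(g1s, pos)
        assert report.functional
        assert not report.sustainable

    def test_positive_circuit_sustained_by_p16_gof_without_damage(
        self, g1s, g1s_circuits
    ):
        (pos,) = [c for c in g1s_circuits if c.sign == "+"]
        mutant = apply_perturbation(g1s, gain_of_function("p16INK4a", 1, 2))
        report = circuit_functionality(mutant, pos)
        assert report.sustainable_inputs == ({"SSB": 0, "DSB": 0},)
        # and the sustained positive circuit indeed yields bistability
        assert len(stable_states(mutant, {"SSB": 0, "DSB": 0})) == 2

    def test_p53_mdm2_loop_not_functional_for_oscillations(self, g1s, g1s_circuits):
        """The two interactions operate at incompatible p53 level ranges.

        Mdm2 only selects between p53 levels 1 and 2, while p53 activates
        Mdm2 already at level 1 — no consistent threshold exists, so the
        negative loop cannot oscillate.
        """
        (loop,) = [c for c in g1s_circuits if set(c.nodes) == {"p53", "Mdm2"}]
        report = circuit_functionality(g1s, loop)
        assert not report.functional
        assert report.threshold_assignments == ()

    def test_multistability_implies_a_sustainable_positive_circuit(self, g1s):
        """Structure/dynamics sanity link on the G1/S clamp variants."""
        for clamp in (gain_of_function("p16INK4a", 1, 2),
                      gain_of_function("p16INK4a", 2)):
            mutant = apply_perturbation(g1s, clamp)
            multistable_inputs = [
                {"SSB": ssb, "DSB": dsb}
                for ssb, dsb in itertools.product(range(3), range(3))
                if len(stable_states(mutant, {"SSB": ssb, "DSB": dsb})) >= 2
            ]
            assert multistable_inputs, "clamp should create multistability"
            circuits = enumerate_circuits(mutant.regulatory_graph())
            positives = [c for c in circuits if c.sign == "+"]
            sustained = set()
            for c in positives:
                rep = circuit_functionality(mutant, c)
                sustained.update(
                    tuple(sorted(a.items())) for a in rep.sustainable_inputs
                )
            for inputs in multistable_inputs:
                assert tuple(sorted(inputs.items())) in sustained

    def test_multistable_random_models_contain_a_positive_candidate_circuit(self):
        """A model with two stable states has a non-negative circuit."""
        checked = 0
        for seed in range(80):
            model = random_model(RandomModelSpec(
                n_components=5, max_level_choices=(1,), n_inputs=1,
                edge_density=0.5, seed=seed,
            ))
            inp = model.inputs[0]
            if any(
                len(stable_states(model, {inp: lvl})) >= 2
                for lvl in range(model.max_level(inp) + 1)
            ):
                circuits = enumerate_circuits(model.regulatory_graph())
                assert any(c.sign in ("+", "undetermined") for c in circuits), seed
                checked += 1
        assert checked >= 5, "random sample must include multistable models"
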