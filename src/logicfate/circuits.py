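"""Regulatory-circuit enumeration, signs, and functionality analysis.

A *circuit* is a simple cycle of the signed regulatory graph; its sign is
the parity of its inhibitory edges.  Positive circuits are the structural
prerequisite for multistability, negative circuits for sustained
oscillations — but a circuit only generates its characteristic dynamics
inside its *functionality context*, the region of state space where every
edge of the circuit is actually decisive.

Functionality is approximated here by threshold-consistent edge
decisiveness.  For an edge ``u -> v``, a pair of thresholds
``(theta_u, theta_v)`` is *decisive in a context* (an assignment of v's
other regulators) when moving ``u`` across ``theta_u`` (from
``theta_u - 1`` to ``theta_u``) flips the predicate
``image(v) >= theta_v``.  A circuit is functional when one threshold per
circuit node can be chosen such that every edge is decisive at the
thresholds of its endpoints in at least one context; the circuit's
functionality context is the per-edge family of such contexts.  The
context is *sustainable* under given inputs when some stable state of the
model realises every edge's context simultaneously.

This is a deliberately simplified, fully documented approximation of the
algebraic functionality-context computation from the circuit-analysis
literature; it is exact enough to separate, e.g., a negative loop whose
two interactions operate at incompatible level ranges (no oscillations)
from one whose thresholds align.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .core import LogicalModel, ModelError
from .dynamics import stable_states

__all__ = [
    "Circuit",
    "FunctionalityReport",
    "enumerate_circuits",
    "edge_decisive_contexts",
    "circuit_functionality",
]


@dataclass(frozen=True)
class Circuit:
    """A simple cycle with edge signs; sign is the parity of inhibitions."""

    nodes: tuple[str, ...]
    edge_signs: tuple[str, ...]

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (self.nodes[i], self.nodes[(i + 1) % len(self.nodes)])
            for i in range(len(self.nodes))
        )

    @property
    def sign(self) -> str:
        if any(s not in ("+", "-") for s in self.edge_signs):
            return "undetermined"
        return "+" if self.edge_signs.count("-") % 2 == 0 else "-"

    def __str__(self) -> str:
        arrows = "".join(
            f"{u} -{'|' if s == '-' else '>'} "
            for (u, _), s in zip(self.edges, self.edge_signs)
        )
        return arrows + self.nodes[0]


def _canonical_rotation(nodes: Sequence[str]) -> tuple[str, ...]:
    """Lexicographically smallest rotation (deterministic circuit identity)."""
    nodes = tuple(nodes)
    rotations = [nodes[i:] + nodes[:i] for i in range(len(nodes))]
    return min(rotations)


def enumerate_circuits(graph: nx.DiGraph) -> list[Circuit]:
    """All simple cycles of a signed digraph, canonically rotated and sorted."""
    circuits = []
    for cycle in nx.simple_cycles(graph):
        nodes = _canonical_rotation(cycle)
        signs = tuple(
            graph.edges[nodes[i], nodes[(i + 1) % len(nodes)]].get("sign", "?")
            for i in range(len(nodes))
        )
        circuits.append(Circuit(nodes=nodes, edge_signs=signs))
    circuits.sort(key=lambda c: (len(c.nodes), c.nodes))
    return circuits


def edge_decisive_contexts(
    model: LogicalModel,
    edge: tuple[str, str],
    thresholds: tuple[int, int] | None = None,
) -> dict[tuple[int, int], list[dict[str, int]]]:
    """Contexts in which an edge is decisive, per threshold pair.

    For edge ``(u, v)`` returns a mapping ``(theta_u, theta_v) -> contexts``
    where each context assigns levels to v's regulators other than u such
    that raising ``u`` from ``theta_u - 1`` to ``theta_u`` flips
    ``image(v) >= theta_v``.  With ``thresholds`` given, only that pair is
    examined.  Decisiveness uses the raw (unclamped) image: clamps freeze
    dynamics but do not rewire the logic.
    """
    u, v = edge
    regs = model.regulators(v)
    if u not in regs:
        raise ModelError(f"{u!r} is not a regulator of {v!r}")
    others = [r for r in regs if r != u]
    max_u = model.max_level(u)
    max_v = model.max_level(v)
    if thresholds is None:
        pairs = [
            (tu, tv)
            for tu in range(1, max_u + 1)
            for tv in range(1, max_v + 1)
        ]
    else:
        pairs = [thresholds]
    result: dict[tuple[int, int], list[dict[str, int]]] = {p: [] for p in pairs}
    ranges = [range(model.max_level(r) + 1) for r in others]
    for combo in itertools.product(*ranges):
        ctx = dict(zip(others, combo))
        for tu, tv in pairs:
            below = dict(ctx, **{u: tu - 1})
            above = dict(ctx, **{u: tu})
            flips = (model.raw_image(below, v) >= tv) != (
                model.raw_image(above, v) >= tv
            )
            if flips:
                result[(tu, tv)].append(dict(ctx))
    return result


@dataclass(frozen=True)
class FunctionalityReport:
    """Outcome of the functionality analysis for one circuit.

    ``functional`` — a threshold-consistent decisive context exists at all;
    ``threshold_assignments`` — the consistent per-node threshold choices;
    ``edge_contexts`` — for each feasible assignment, the per-edge decisive
    contexts; ``sustainable_inputs`` — input assignments under which some
    stable state of the model realises every edge's context (empty means
    the circuit cannot generate its characteristic dynamics anywhere the
    system can rest).
    """

    circuit: Circuit
    functional: bool
    threshold_assignments: tuple[dict[str, int], ...]
    edge_contexts: dict[tuple[tuple[str, str], tuple[int, int]], tuple[dict[str, int], ...]] = field(
        repr=False, default_factory=dict
    )
    sustainable_inputs: tuple[dict[str, int], ...] = ()

    @property
    def sustainable(self) -> bool:
        return bool(self.sustainable_inputs)


def _state_matches_context(
    state: Mapping[str, int], contexts: Sequence[Mapping[str, int]]
) -> bool:
    return any(all(state[k] == lvl for k, lvl in ctx.items()) for ctx in contexts)


def circuit_functionality(
    model: LogicalModel,
    circuit: Circuit,
    input_assignments: Sequence[Mapping[str, int]] | None = None,
) -> FunctionalityReport:
    """Threshold-consistent functionality analysis of one circuit.

    ``input_assignments`` defaults to every combination of input levels
    (within clamp windows).  Sustainability is assessed against the stable
    states of the model as given, i.e. including its clamps.
    """
    nodes = circuit.nodes
    per_node_thresholds = [range(1, model.max_level(n) + 1) for n in nodes]
    feasible: list[dict[str, int]] = []
    contexts_by_edge: dict = {}
    for combo in itertools.product(*per_node_thresholds):
        theta = dict(zip(nodes, combo))
        edge_ctx = {}
        ok = True
        for u, v in circuit.edges:
            pair = (theta[u], theta[v])
            ctxs = edge_decisive_contexts(model, (u, v), thresholds=pair)[pair]
            if not ctxs:
                ok = False
                break
            edge_ctx[((u, v), pair)] = tuple(ctxs)
        if ok:
            feasible.append(theta)
            contexts_by_edge.update(edge_ctx)
    if not feasible:
        return FunctionalityReport(circuit, False, ())

    if input_assignments is None:
        windows = [model.clamp_window(n) for n in model.inputs]
        input_assignments = [
            dict(zip(model.inputs, combo))
            for combo in itertools.product(
                *(range(lo, hi + 1) for lo, hi in windows)
            )
        ]
    sustainable = []
    for assignment in input_assignments:
        states = stable_states(model, assignment)
        hit = False
        for theta in feasible:
            for s in states:
                if all(
                    _state_matches_context(
                        s, contexts_by_edge[((u, v), (theta[u], theta[v]))]
                    )
                    for u, v in circuit.edges
                ):
                    hit = True
                    break
            if hit:
                break
        if hit:
            sustainable.append(dict(assignment))
    return FunctionalityReport(
        circuit,
        True,
        tuple(feasible),
        contexts_by_edge,
        tuple(sustainable),
    )
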