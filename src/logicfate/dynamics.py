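"""State-transition dynamics: successors, stable states, attractors.

Updates are *unit-step*: an enabled component moves one level toward its
image, never jumps.  Under the asynchronous scheme each enabled component
yields one successor (non-determinism is explicit in the successor set);
under the synchronous scheme all enabled components move together in a
single successor.  Stable states (fixed points of the image function) are
scheme-independent.

Stable states are enumerated by feedback-vertex-set decomposition: inputs
are fixed, the dependency graph of the remaining components is reduced to a
DAG by removing a small feedback vertex set, the feedback components' level
assignments are enumerated, the rest is propagated in topological order,
and assignments whose feedback images are inconsistent are discarded.  An
exhaustive scan (:func:`brute_force_stable_states`) provides the
independent oracle for testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .core import LogicalModel, ModelError

__all__ = [
    "successors",
    "stable_states",
    "brute_force_stable_states",
    "attractors",
    "Attractor",
    "StateSpaceTooLarge",
]

SCHEMES = ("asynchronous", "synchronous")


class StateSpaceTooLarge(ModelError):
    """The requested exhaustive computation exceeds the configured cap."""


def _check_scheme(scheme: str) -> None:
    if scheme not in SCHEMES:
        raise ModelError(f"unknown update scheme {scheme!r}; expected one of {SCHEMES}")


def successors(
    model: LogicalModel, state: Mapping[str, int], scheme: str = "asynchronous"
) -> set[tuple[tuple[str, int], ...]]:
    """Successor states under the given update scheme.

    States are returned as sorted ``((name, level), ...)`` tuples (hashable).
    A stable state has no successors.
    """
    _check_scheme(scheme)
    comp = model.compiled
    cur = comp.state_tuple(state)
    targets = comp.targets(cur)
    moves = [
        (i, 1 if targets[i] > cur[i] else -1)
        for i in range(comp.n)
        if targets[i] != cur[i]
    ]
    result: set[tuple[tuple[str, int], ...]] = set()
    if scheme == "asynchronous":
        for i, step in moves:
            nxt = list(cur)
            nxt[i] += step
            result.add(tuple(zip(comp.names, nxt)))
    elif moves:
        nxt = list(cur)
        for i, step in moves:
            nxt[i] += step
        result.add(tuple(zip(comp.names, nxt)))
    return result


def _effective_inputs(
    model: LogicalModel, input_assignment: Mapping[str, int]
) -> dict[str, int]:
    """Input levels with clamps folded in (clamping an input fixes it)."""
    values = {}
    for name in model.inputs:
        if name not in input_assignment:
            raise ModelError(f"input component {name!r} has no assigned level")
        lo, hi = model.clamp_window(name)
        values[name] = min(max(int(input_assignment[name]), lo), hi)
    return values


def _greedy_fvs(graph: nx.DiGraph) -> list[str]:
    """A small feedback vertex set by greedy removal (not provably minimum).

    Self-loop nodes are forced into the set; otherwise the node with the
    largest in*out degree product inside a non-trivial strongly connected
    component is removed until the graph is acyclic.
    """
    g = graph.copy()
    fvs = []
    for node in [n for n in g.nodes if g.has_edge(n, n)]:
        fvs.append(node)
        g.remove_node(node)
    while True:
        cyclic = [scc for scc in nx.strongly_connected_components(g) if len(scc) > 1]
        if not cyclic:
            break
        scc = max(cyclic, key=len)
        node = max(scc, key=lambda n: (g.in_degree(n) * g.out_degree(n), n))
        fvs.append(node)
        g.remove_node(node)
    return fvs


def stable_states(
    model: LogicalModel, input_assignment: Mapping[str, int]
) -> list[dict[str, int]]:
    """All fixed points of the image function with the given input levels.

    Uses feedback-vertex-set decomposition (see module docstring); the
    result is sorted canonically by component levels.
    """
    inputs = _effective_inputs(model, input_assignment)
    non_inputs = [c.name for c in model.components if c.kind != "input"]
    dep = nx.DiGraph()
    dep.add_nodes_from(non_inputs)
    for v in non_inputs:
        for u in model.regulators(v):
            if u in dep:
                dep.add_edge(u, v)
    fvs = _greedy_fvs(dep)
    rest = dep.copy()
    rest.remove_nodes_from(fvs)
    order = list(nx.topological_sort(rest))

    found = []
    windows = {n: model.clamp_window(n) for n in non_inputs}
    fvs_ranges = [range(windows[n][0], windows[n][1] + 1) for n in fvs]
    for combo in itertools.product(*fvs_ranges):
        state = dict(inputs)
        state.update(zip(fvs, combo))
        for n in order:
            state[n] = model.image(state, n)
        if all(model.image(state, n) == state[n] for n in fvs):
            # safety: the propagated state must be a genuine fixed point
            if model.is_stable(state):
                found.append({n: state[n] for n in model.names})
    found.sort(key=lambda s: tuple(s[n] for n in model.names))
    return found


def _restricted_space_size(model: LogicalModel) -> int:
    size = 1
    for c in model.components:
        if c.kind != "input":
            lo, hi = model.clamp_window(c.name)
            size *= hi - lo + 1
    return size


def brute_force_stable_states(
    model: LogicalModel,
    input_assignment: Mapping[str, int],
    cap: int = 10**7,
) -> list[dict[str, int]]:
    """Exhaustive fixed-point scan over the clamp-respecting subspace.

    Test oracle for :func:`stable_states`; refuses (never truncates) when
    the subspace exceeds ``cap`` states.
    """
    size = _restricted_space_size(model)
    if size > cap:
        raise StateSpaceTooLarge(
            f"restricted state space has {size} states, above the cap of {cap}"
        )
    inputs = _effective_inputs(model, input_assignment)
    comp = model.compiled
    non_inputs = [i for i in range(comp.n) if not comp.is_input[i]]
    base = [0] * comp.n
    for name, lvl in inputs.items():
        base[comp.index[name]] = lvl
    ranges = [
        range(comp.windows[i][0], comp.windows[i][1] + 1) for i in non_inputs
    ]
    found = []
    for combo in itertools.product(*ranges):
        state = list(base)
        for i, lvl in zip(non_inputs, combo):
            state[i] = lvl
        if comp.targets(state) == state:
            found.append(comp.state_dict(state))
    found.sort(key=lambda s: tuple(s[n] for n in model.names))
    return found


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the state-transition graph.

    ``kind`` is ``"stable_state"`` for a singleton fixed point and
    ``"complex"`` for a cyclic attractor of two or more states.
    """

    states: frozenset[tuple[tuple[str, int], ...]]
    kind: str

    def __len__(self) -> int:
        return len(self.states)

    def as_dicts(self) -> list[dict[str, int]]:
        return sorted(
            (dict(s) for s in self.states),
            key=lambda d: tuple(d.values()),
        )


def _full_restricted_states(
    model: LogicalModel, inputs: Mapping[str, int]
) -> Iterable[tuple[int, ...]]:
    comp = model.compiled
    base = [0] * comp.n
    for name, lvl in inputs.items():
        base[comp.index[name]] = lvl
    non_inputs = [i for i in range(comp.n) if not comp.is_input[i]]
    ranges = [range(comp.windows[i][0], comp.windows[i][1] + 1) for i in non_inputs]
    for combo in itertools.product(*ranges):
        state = list(base)
        for i, lvl in zip(non_inputs, combo):
            state[i] = lvl
        yield tuple(state)


def attractors(
    model: LogicalModel,
    input_assignment: Mapping[str, int],
    scheme: str = "asynchronous",
    cap: int = 10**6,
    initial_states: Iterable[Mapping[str, int]] | None = None,
) -> list[Attractor]:
    """Terminal SCCs of the (restricted) state-transition graph.

    With ``initial_states`` the graph is restricted to the set reachable
    from them; otherwise the full clamp-respecting subspace with fixed
    inputs is explored.  Refuses when more than ``cap`` states would be
    visited.
    """
    _check_scheme(scheme)
    inputs = _effective_inputs(model, input_assignment)
    comp = model.compiled

    def succ_tuples(cur: tuple[int, ...]) -> list[tuple[int, ...]]:
        targets = comp.targets(cur)
        moves = [
            (i, 1 if targets[i] > cur[i] else -1)
            for i in range(comp.n)
            if targets[i] != cur[i]
        ]
        if scheme == "synchronous":
            if not moves:
                return []
            nxt = list(cur)
            for i, step in moves:
                nxt[i] += step
            return [tuple(nxt)]
        out = []
        for i, step in moves:
            nxt = list(cur)
            nxt[i] += step
            out.append(tuple(nxt))
        return out

    g = nx.DiGraph()
    if initial_states is None:
        size = _restricted_space_size(model)
        if size > cap:
            raise StateSpaceTooLarge(
                f"restricted state space has {size} states, above the cap of {cap}; "
                "provide initial_states to explore a reachable subset"
            )
        for cur in _full_restricted_states(model, inputs):
            g.add_node(cur)
            for nxt in succ_tuples(cur):
                g.add_edge(cur, nxt)
    else:
        frontier = []
        for s in initial_states:
            st = list(comp.state_tuple(s))
            for name, lvl in inputs.items():
                st[comp.index[name]] = lvl
            frontier.append(tuple(st))
        seen = set(frontier)
        while frontier:
            cur = frontier.pop()
            g.add_node(cur)
            for nxt in succ_tuples(cur):
                g.add_edge(cur, nxt)
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
                    if len(seen) > cap:
                        raise StateSpaceTooLarge(
                            f"reachable set exceeds the cap of {cap} states"
                        )

    condensation = nx.condensation(g)
    result = []
    for scc_id in condensation.nodes:
        if condensation.out_degree(scc_id) != 0:
            continue
        members = condensation.nodes[scc_id]["members"]
        states = frozenset(tuple(zip(comp.names, s)) for s in members)
        kind = (
            "stable_state"
            if len(members) == 1 and g.out_degree(next(iter(members))) == 0
            else "complex"
        )
        result.append(Attractor(states=states, kind=kind))
    result.sort(key=lambda a: sorted(a.states))
    return result
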