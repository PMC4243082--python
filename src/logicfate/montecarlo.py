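"""Monte-Carlo estimation of attractor reach probabilities.

The sampling scheme is an unbiased asynchronous random walk: initial states
are drawn uniformly from the clamp-respecting state space with inputs
fixed; at each step one of the enabled unit transitions is chosen uniformly
at random; a run ends when it hits a stable state (recorded against that
attractor) or when the step budget is exhausted (recorded as unresolved,
never silently dropped).  The per-attractor hit frequency estimates the
probability of reaching that attractor from a random state.

For small models the same uniform-choice walk admits an exact answer:
:func:`exact_absorption_probabilities` solves the absorption linear system
on the full state-transition graph and serves as the independent oracle
for the estimator.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import LogicalModel, ModelError
from .dynamics import StateSpaceTooLarge, _effective_inputs, stable_states

__all__ = [
    "McConfig",
    "McEstimate",
    "simulate_trajectory",
    "estimate_probabilities",
    "exact_absorption_probabilities",
    "random_initial_state",
]


@dataclass(frozen=True)
class McConfig:
    """Sampling configuration: 10^4 runs of at most 10^4 steps by default."""

    n_runs: int = 10_000
    max_steps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.max_steps < 1:
            raise ModelError("n_runs and max_steps must be positive")


@dataclass(frozen=True)
class McEstimate:
    """Per-attractor hit counts, frequencies and binomial 95% intervals.

    ``attractors`` are the stable states (as name->level dicts) in canonical
    order; ``probabilities`` and the unresolved fraction sum to one.  A
    ``warning`` is set when more than 1% of runs did not resolve within the
    step budget.
    """

    attractors: tuple[dict[str, int], ...]
    counts: tuple[int, ...]
    n_runs: int
    unresolved: int
    seed: int

    @property
    def probabilities(self) -> tuple[float, ...]:
        return tuple(c / self.n_runs for c in self.counts)

    @property
    def unresolved_fraction(self) -> float:
        return self.unresolved / self.n_runs

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        """Normal-approximation 95% confidence intervals, clipped to [0,1]."""
        out = []
        for c in self.counts:
            p = c / self.n_runs
            half = 1.96 * math.sqrt(p * (1 - p) / self.n_runs)
            out.append((max(0.0, p - half), min(1.0, p + half)))
        return tuple(out)

    @property
    def warning(self) -> str | None:
        if self.unresolved_fraction > 0.01:
            return (
                f"{self.unresolved} of {self.n_runs} runs "
                f"({100 * self.unresolved_fraction:.1f}%) did not reach an "
                "attractor within the step budget"
            )
        return None


def random_initial_state(
    model: LogicalModel,
    input_assignment: Mapping[str, int],
    rng: random.Random,
) -> dict[str, int]:
    """Uniform draw from the clamp-respecting space with inputs fixed."""
    inputs = _effective_inputs(model, input_assignment)
    state = {}
    for c in model.components:
        if c.kind == "input":
            state[c.name] = inputs[c.name]
        else:
            lo, hi = model.clamp_window(c.name)
            state[c.name] = rng.randint(lo, hi)
    return state


def _walk(compiled, state: list[int], rng: random.Random, max_steps: int):
    """Uniform-choice asynchronous walk; returns (final tuple | None, steps)."""
    n = compiled.n
    targets = [compiled.target(state, i) for i in range(n)]
    dependents = compiled.dependents
    for step in range(max_steps + 1):
        enabled = [i for i in range(n) if targets[i] != state[i]]
        if not enabled:
            return tuple(state), step
        if step == max_steps:
            break
        i = enabled[rng.randrange(len(enabled))]
        state[i] += 1 if targets[i] > state[i] else -1
        for j in dependents[i]:
            targets[j] = compiled.target(state, j)
    return None, max_steps


def simulate_trajectory(
    model: LogicalModel,
    input_assignment: Mapping[str, int],
    initial: Mapping[str, int],
    rng: random.Random,
    max_steps: int = 10_000,
) -> tuple[dict[str, int] | None, int]:
    """One asynchronous random walk from ``initial``.

    Returns ``(stable_state, steps)`` on absorption, ``(None, max_steps)``
    when unresolved.  Inputs from ``input_assignment`` override the initial
    state's input levels.
    """
    comp = model.compiled
    inputs = _effective_inputs(model, input_assignment)
    state = list(comp.state_tuple(initial))
    for name, lvl in inputs.items():
        state[comp.index[name]] = lvl
    final, steps = _walk(comp, state, rng, max_steps)
    if final is None:
        return None, steps
    return comp.state_dict(final), steps


def estimate_probabilities(
    model: LogicalModel,
    input_assignment: Mapping[str, int],
    config: McConfig = McConfig(),
) -> McEstimate:
    """Estimate attractor reach probabilities from uniform random states.

    The model's stable states under the inputs are precomputed for
    membership/identity; a walk that rests at a fixed point outside that
    set would indicate an engine bug and raises.
    """
    attractor_states = stable_states(model, input_assignment)
    comp = model.compiled
    key_of = {comp.state_tuple(s): k for k, s in enumerate(attractor_states)}
    counts = [0] * len(attractor_states)
    unresolved = 0
    rng = random.Random(config.seed)
    inputs = _effective_inputs(model, input_assignment)
    input_idx = [(comp.index[n], lvl) for n, lvl in inputs.items()]
    windows = comp.windows
    non_inputs = [i for i in range(comp.n) if not comp.is_input[i]]
    for _ in range(config.n_runs):
        state = [0] * comp.n
        for i, lvl in input_idx:
            state[i] = lvl
        for i in non_inputs:
            lo, hi = windows[i]
            state[i] = rng.randint(lo, hi)
        final, _steps = _walk(comp, state, rng, config.max_steps)
        if final is None:
            unresolved += 1
            continue
        try:
            counts[key_of[final]] += 1
        except KeyError:
            raise ModelError(
                "walk rested at a fixed point missing from the enumerated "
                f"stable states: {comp.state_dict(final)}"
            ) from None
    estimate = McEstimate(
        attractors=tuple(attractor_states),
        counts=tuple(counts),
        n_runs=config.n_runs,
        unresolved=unresolved,
        seed=config.seed,
    )
    if estimate.warning:
        warnings.warn(estimate.warning, stacklevel=2)
    return estimate


def exact_absorption_probabilities(
    model: LogicalModel,
    input_assignment: Mapping[str, int],
    cap: int = 2**14,
) -> tuple[tuple[dict[str, int], ...], np.ndarray]:
    """Exact reach probabilities of the uniform-choice asynchronous walk.

    Enumerates the full clamp-respecting state space with fixed inputs,
    builds the Markov chain in which each enabled unit transition is chosen
    uniformly, and solves the absorption system for a uniform initial
    distribution.  Only valid when every attractor is a stable state; a
    complex terminal SCC raises.  Intended as a small-model oracle.
    """
    from .dynamics import _full_restricted_states

    inputs = _effective_inputs(model, input_assignment)
    comp = model.compiled
    states = list(_full_restricted_states(model, inputs))
    if len(states) > cap:
        raise StateSpaceTooLarge(
            f"state space has {len(states)} states, above the cap of {cap}"
        )
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    succ: list[list[int]] = []
    for s in states:
        targets = comp.targets(list(s))
        moves = [
            (i, 1 if targets[i] > s[i] else -1)
            for i in range(comp.n)
            if targets[i] != s[i]
        ]
        nxt = []
        for i, step in moves:
            t = list(s)
            t[i] += step
            nxt.append(index[tuple(t)])
        succ.append(nxt)
    absorbing = [i for i, nxt in enumerate(succ) if not nxt]
    transient = [i for i, nxt in enumerate(succ) if nxt]
    # every terminal SCC must be a singleton fixed point for absorption
    # probabilities to exhaust the mass
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i, nxt in enumerate(succ):
        g.add_edges_from((i, j) for j in nxt)
    cond = nx.condensation(g)
    for scc_id in cond.nodes:
        members = cond.nodes[scc_id]["members"]
        if cond.out_degree(scc_id) == 0 and len(members) > 1:
            raise ModelError(
                "model has a complex attractor; exact absorption "
                "probabilities are only defined for stable-state attractors"
            )
    t_index = {s: k for k, s in enumerate(transient)}
    a_index = {s: k for k, s in enumerate(absorbing)}
    nt, na = len(transient), len(absorbing)
    Q = np.zeros((nt, nt))
    R = np.zeros((nt, na))
    for s in transient:
        p = 1.0 / len(succ[s])
        for j in succ[s]:
            if j in t_index:
                Q[t_index[s], t_index[j]] += p
            else:
                R[t_index[s], a_index[j]] += p
    B = np.linalg.solve(np.eye(nt) - Q, R) if nt else np.zeros((0, na))
    # uniform initial distribution over all states
    reach = np.zeros(na)
    for s in absorbing:
        reach[a_index[s]] += 1.0
    if nt:
        reach += B.sum(axis=0)
    reach /= n
    ordered = sorted(range(na), key=lambda k: states[absorbing[k]])
    attractor_dicts = tuple(
        comp.state_dict(states[absorbing[k]]) for k in ordered
    )
    return attractor_dicts, reach[ordered]
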