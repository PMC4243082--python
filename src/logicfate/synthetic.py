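"""Random small multi-valued models for oracle-based engine testing.

The generator draws, for every non-input component, an explicit image
table over its regulators' level combinations and then reads the rules off
that table (one rule per positive target level, a disjunction of exact
regulator assignments).  Rule exclusivity therefore holds *by
construction*, which keeps the engine's exclusivity validation genuinely
independent when it runs on hand-written models.

These models make no attempt at biologically realistic topology; they
exist so that decomposition-based stable-state search, sign computation,
circuit enumeration and the Monte-Carlo estimator can each be compared
against brute-force oracles on thousands of seeded instances.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .core import And, Atom, Component, LogicalModel, ModelError, Or, Rule

__all__ = ["RandomModelSpec", "random_model", "random_state"]


@dataclass(frozen=True)
class RandomModelSpec:
    """Shape of a random model; identical spec + seed gives identical model."""

    n_components: int = 5
    max_level_choices: tuple[int, ...] = (1, 2)
    n_inputs: int = 1
    edge_density: float = 0.5
    max_regulators: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_components <= 12):
            raise ModelError("n_components must be in [1, 12]")
        if self.n_inputs < 0 or self.n_inputs >= self.n_components:
            raise ModelError("n_inputs must leave at least one non-input component")
        if not all(m in (1, 2, 3) for m in self.max_level_choices):
            raise ModelError("max_level_choices must be a subset of {1, 2, 3}")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ModelError("edge_density must be a fraction")


def random_model(spec: RandomModelSpec) -> LogicalModel:
    """Generate a random model that always passes ``validate()``."""
    rng = random.Random(spec.seed)
    components = []
    for i in range(spec.n_components):
        kind = "input" if i < spec.n_inputs else "internal"
        components.append(
            Component(
                name=f"X{i}",
                max_level=rng.choice(spec.max_level_choices),
                kind=kind,
            )
        )
    names = [c.name for c in components]
    rules: list[Rule] = []
    for c in components:
        if c.kind == "input":
            continue
        candidates = [n for n in names]
        regs = [n for n in candidates if rng.random() < spec.edge_density]
        rng.shuffle(regs)
        regs = sorted(regs[: spec.max_regulators], key=names.index)
        if not regs:
            continue  # constant component, image 0
        by_name = {x.name: x for x in components}
        ranges = [range(by_name[r].max_level + 1) for r in regs]
        # explicit image table, then rules read off it
        buckets: dict[int, list[tuple[int, ...]]] = {}
        for combo in itertools.product(*ranges):
            target = rng.randint(0, c.max_level)
            if target > 0:
                buckets.setdefault(target, []).append(combo)
        for target, combos in sorted(buckets.items()):
            disjuncts = []
            for combo in combos:
                atoms = [Atom(r, lvl, lvl) for r, lvl in zip(regs, combo)]
                disjuncts.append(atoms[0] if len(atoms) == 1 else And(*atoms))
            cond = disjuncts[0] if len(disjuncts) == 1 else Or(*disjuncts)
            rules.append(Rule(c.name, target, cond))
    return LogicalModel(
        components,
        rules,
        name=f"random-{spec.seed}",
        metadata={"generator": "synthetic image-table", "spec_seed": spec.seed},
    )


def random_state(
    model: LogicalModel,
    rng: random.Random,
    input_assignment: dict[str, int] | None = None,
) -> dict[str, int]:
    """Uniform draw from the clamp-respecting state space.

    With ``input_assignment`` given, inputs are fixed to it (clipped into
    their clamp windows) instead of being drawn.
    """
    state = {}
    for c in model.components:
        lo, hi = model.clamp_window(c.name)
        if c.kind == "input" and input_assignment is not None:
            state[c.name] = min(max(int(input_assignment[c.name]), lo), hi)
        else:
            state[c.name] = rng.randint(lo, hi)
    return state
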