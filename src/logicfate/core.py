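"""Generic multi-valued (Thomas-style) logical models.

A model is a set of components, each holding a small integer activity level
in ``[0, max_level]``, together with logical rules.  A rule assigns a target
level to a component under a condition over the levels of its regulators.
The *image* of a state is the vector of target levels the rules dictate:
the level of the unique satisfied rule for each component, 0 if no rule is
satisfied, the current level for input components.  Fixed points of the
image function are the model's stable states.

Rules for one component must be mutually exclusive: at most one condition
may hold for any combination of regulator levels.  This is validated
exhaustively (regulator subspaces are small) rather than silently
tie-broken, so an overlapping pair of rules is reported as a model bug.

Components may be *clamped* to a level interval (used for loss- and
gain-of-function perturbations): the raw image is clipped into the
interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Component",
    "Atom",
    "Not",
    "And",
    "Or",
    "Condition",
    "Rule",
    "LogicalModel",
    "Violation",
    "ModelError",
    "ExclusivityError",
]

State = Mapping[str, int]

KINDS = ("input", "internal", "output")


class ModelError(ValueError):
    """A structural inconsistency in a logical model."""


class ExclusivityError(ModelError):
    """Two rules of the same component are satisfied in the same state."""


@dataclass(frozen=True)
class Component:
    """A model component with levels 0..max_level.

    ``kind`` distinguishes constant inputs (never regulated; they embody
    extrinsic conditions such as damage intensity), ordinary internal
    nodes, and read-out outputs (regulated but regulating nothing).
    """

    name: str
    max_level: int = 1
    kind: str = "internal"

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise ModelError(f"component {self.name!r}: max_level must be >= 1")
        if self.kind not in KINDS:
            raise ModelError(f"component {self.name!r}: kind must be one of {KINDS}")


class Condition:
    """Base class for condition expression trees (Atom / Not / And / Or)."""

    def evaluate(self, state: State) -> bool:
        raise NotImplementedError

    def regulators(self) -> frozenset[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_string()!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Condition) and self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())


@dataclass(frozen=True, eq=False)
class Atom(Condition):
    """Satisfied by state ``x`` iff ``lo <= x[regulator] <= hi``."""

    regulator: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ModelError(
                f"atom on {self.regulator!r}: invalid interval [{self.lo},{self.hi}]"
            )

    def evaluate(self, state: State) -> bool:
        try:
            level = state[self.regulator]
        except KeyError:
            raise ModelError(
                f"state does not assign a level to regulator {self.regulator!r}"
            ) from None
        return self.lo <= level <= self.hi

    def regulators(self) -> frozenset[str]:
        return frozenset((self.regulator,))

    def to_string(self) -> str:
        if self.lo == self.hi:
            return f"{self.regulator} = {self.lo}-{self.lo}"
        return f"{self.regulator} = {self.lo}-{self.hi}"


@dataclass(frozen=True, eq=False)
class Not(Condition):
    term: Condition

    def evaluate(self, state: State) -> bool:
        return not self.term.evaluate(state)

    def regulators(self) -> frozenset[str]:
        return self.term.regulators()

    def to_string(self) -> str:
        return f"NOT ({self.term.to_string()})"


@dataclass(frozen=True, eq=False)
class And(Condition):
    terms: tuple[Condition, ...]

    def __init__(self, *terms: Condition) -> None:
        object.__setattr__(self, "terms", tuple(terms))
        if not self.terms:
            raise ModelError("AND requires at least one term")

    def evaluate(self, state: State) -> bool:
        return all(t.evaluate(state) for t in self.terms)

    def regulators(self) -> frozenset[str]:
        return frozenset().union(*(t.regulators() for t in self.terms))

    def to_string(self) -> str:
        return " AND ".join(_maybe_paren(t) for t in self.terms)


@dataclass(frozen=True, eq=False)
class Or(Condition):
    terms: tuple[Condition, ...]

    def __init__(self, *terms: Condition) -> None:
        object.__setattr__(self, "terms", tuple(terms))
        if not self.terms:
            raise ModelError("OR requires at least one term")

    def evaluate(self, state: State) -> bool:
        return any(t.evaluate(state) for t in self.terms)

    def regulators(self) -> frozenset[str]:
        return frozenset().union(*(t.regulators() for t in self.terms))

    def to_string(self) -> str:
        return " OR ".join(_maybe_paren(t, in_or=True) for t in self.terms)


def _maybe_paren(term: Condition, in_or: bool = False) -> str:
    # AND binds tighter than OR; parenthesise an OR inside an AND (and
    # nested ORs, to keep the canonical form unambiguous on re-parse).
    s = term.to_string()
    if isinstance(term, Or):
        return f"({s})"
    if in_or and isinstance(term, And):
        return s
    return s


@dataclass(frozen=True)
class Rule:
    """``component`` is driven toward ``target_level`` while ``condition`` holds."""

    component: str
    target_level: int
    condition: Condition

    def __post_init__(self) -> None:
        if self.target_level < 1:
            raise ModelError(
                f"rule for {self.component!r}: target_level must be >= 1 "
                "(level 0 is the implicit default)"
            )


@dataclass(frozen=True)
class Violation:
    """A single validation finding (machine-readable kind + human message)."""

    kind: str
    component: str
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.component}: {self.message}"


class LogicalModel:
    """A multi-valued logical model: components, rules, optional clamps.

    Parameters
    ----------
    components
        Ordered collection of :class:`Component`; the order fixes the
        canonical component order of states, tables and serialised files.
    rules
        Rules for non-input components.  A component with no satisfied rule
        has image 0; explicit level-0 rules are never written.
    clamps
        Optional mapping ``name -> (lo, hi)``; the image of a clamped
        component is clipped into the interval (loss/gain of function).
    """

    def __init__(
        self,
        components: Iterable[Component],
        rules: Iterable[Rule],
        clamps: Mapping[str, tuple[int, int]] | None = None,
        name: str = "",
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        self.components: tuple[Component, ...] = tuple(components)
        self.rules: tuple[Rule, ...] = tuple(rules)
        self.clamps: dict[str, tuple[int, int]] = {
            k: (int(lo), int(hi)) for k, (lo, hi) in (clamps or {}).items()
        }
        self.name = name
        self.metadata = dict(metadata or {})

        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelError(f"duplicate component names: {dupes}")
        self._by_name = {c.name: c for c in self.components}
        self._index = {c.name: i for i, c in enumerate(self.components)}
        self._rules_of: dict[str, list[Rule]] = {c.name: [] for c in self.components}
        for r in self.rules:
            if r.component not in self._by_name:
                raise ModelError(f"rule targets unknown component {r.component!r}")
            self._rules_of[r.component].append(r)
        for comp, (lo, hi) in self.clamps.items():
            if comp not in self._by_name:
                raise ModelError(f"clamp on unknown component {comp!r}")
            if not (0 <= lo <= hi <= self._by_name[comp].max_level):
                raise ModelError(
                    f"clamp on {comp!r}: interval [{lo},{hi}] outside "
                    f"[0,{self._by_name[comp].max_level}]"
                )
        self._regulators: dict[str, tuple[str, ...]] = {}
        for c in self.components:
            regs: set[str] = set()
            for r in self._rules_of[c.name]:
                regs |= r.condition.regulators()
            unknown = regs - set(names)
            if unknown:
                raise ModelError(
                    f"rules of {c.name!r} refer to unknown regulators {sorted(unknown)}"
                )
            self._regulators[c.name] = tuple(sorted(regs, key=self._index.__getitem__))

    # -- basic accessors ---------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.kind == "input")

    def component(self, name: str) -> Component:
        try:
            return self._by_name[name]
        except KeyError:
            raise ModelError(f"unknown component {name!r}") from None

    def max_level(self, name: str) -> int:
        return self.component(name).max_level

    def rules_of(self, name: str) -> tuple[Rule, ...]:
        return tuple(self._rules_of[name])

    def regulators(self, name: str) -> tuple[str, ...]:
        """Components appearing in some rule of ``name`` (canonical order)."""
        return self._regulators[name]

    def clamp_window(self, name: str) -> tuple[int, int]:
        """The admissible level interval of ``name`` (clamp or full range)."""
        return self.clamps.get(name, (0, self.component(name).max_level))

    def with_clamps(self, extra: Mapping[str, tuple[int, int]]) -> "LogicalModel":
        """A copy of the model with additional clamps (originals kept)."""
        merged = dict(self.clamps)
        merged.update({k: (int(lo), int(hi)) for k, (lo, hi) in extra.items()})
        return LogicalModel(
            self.components, self.rules, merged, name=self.name, metadata=self.metadata
        )

    def without_clamps(self) -> "LogicalModel":
        return LogicalModel(
            self.components, self.rules, None, name=self.name, metadata=self.metadata
        )

    # -- the image function ------------------------------------------------

    def raw_image(self, state: State, name: str) -> int:
        """Image before clamping: unique satisfied rule's target, else 0."""
        comp = self.component(name)
        if comp.kind == "input":
            return int(state[name])
        satisfied = [r for r in self._rules_of[name] if r.condition.evaluate(state)]
        if len(satisfied) > 1:
            levels = sorted(r.target_level for r in satisfied)
            raise ExclusivityError(
                f"component {name!r}: rules for target levels {levels} are "
                f"simultaneously satisfied (model bug, not a tie to break)"
            )
        return satisfied[0].target_level if satisfied else 0

    def image(self, state: State, name: str) -> int:
        """Target level of ``name`` at ``state`` (clamped if applicable)."""
        value = self.raw_image(state, name)
        lo, hi = self.clamp_window(name)
        return min(max(value, lo), hi)

    def image_vector(self, state: State) -> dict[str, int]:
        """The image K(x) for every component; fixed points are stable states."""
        return {c.name: self.image(state, c.name) for c in self.components}

    def is_stable(self, state: State) -> bool:
        return all(self.image(state, c.name) == state[c.name] for c in self.components)

    # -- validation ----------------------------------------------------------

    def validate(self) -> list[Violation]:
        """Exhaustive structural validation; empty list means the model is sound.

        Checks name uniqueness and bounds at construction time are
        complemented here by: rule target bounds, rules on input
        components, outputs acting as regulators, and exhaustive rule
        exclusivity over every component's regulator subspace.
        """
        violations: list[Violation] = []
        for c in self.components:
            rules = self._rules_of[c.name]
            for r in rules:
                if r.target_level > c.max_level:
                    violations.append(
                        Violation(
                            "target_bounds",
                            c.name,
                            f"rule target {r.target_level} exceeds max_level "
                            f"{c.max_level}",
                        )
                    )
            if c.kind == "input" and rules:
                violations.append(
                    Violation(
                        "input_regulated",
                        c.name,
                        "input components are constant and must have no rules",
                    )
                )
        regulating = {
            reg for c in self.components for reg in self._regulators[c.name]
        }
        for c in self.components:
            if c.kind == "output" and c.name in regulating:
                violations.append(
                    Violation(
                        "output_regulates",
                        c.name,
                        "output components must not regulate other components",
                    )
                )
        # Exhaustive exclusivity over each component's regulator subspace.
        for c in self.components:
            rules = self._rules_of[c.name]
            if len(rules) < 2:
                continue
            regs = self._regulators[c.name]
            ranges = [range(self.component(r).max_level + 1) for r in regs]
            for combo in itertools.product(*ranges):
                local = dict(zip(regs, combo))
                satisfied = [
                    r.target_level for r in rules if r.condition.evaluate(local)
                ]
                if len(satisfied) > 1:
                    violations.append(
                        Violation(
                            "exclusivity",
                            c.name,
                            f"rules for targets {sorted(satisfied)} all satisfied "
                            f"at regulator state {local}",
                        )
                    )
                    break  # one witness per component is enough
        return violations

    # -- the signed regulatory graph -----------------------------------------

    def regulatory_graph(self) -> nx.DiGraph:
        """Signed interaction graph derived from the rules.

        An edge ``u -> v`` exists iff ``u`` appears in some rule of ``v``.
        Its sign is determined by exhaustive monotonicity of the (raw)
        image of ``v`` as ``u`` varies over its range, across all contexts
        of the remaining regulators: ``+`` if the image can only increase
        with ``u``, ``-`` if it can only decrease, ``dual`` if both occur,
        ``0`` if ``u`` never changes the image.
        """
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.names)
        for v in self.components:
            regs = self._regulators[v.name]
            for u in regs:
                others = [r for r in regs if r != u]
                ranges = [range(self.component(r).max_level + 1) for r in others]
                increases = decreases = False
                for combo in itertools.product(*ranges):
                    ctx = dict(zip(others, combo))
                    prev = None
                    for lvl in range(self.component(u).max_level + 1):
                        ctx[u] = lvl
                        img = self.raw_image(ctx, v.name)
                        if prev is not None:
                            if img > prev:
                                increases = True
                            elif img < prev:
                                decreases = True
                        prev = img
                sign = {
                    (True, False): "+",
                    (False, True): "-",
                    (True, True): "dual",
                    (False, False): "0",
                }[(increases, decreases)]
                g.add_edge(u, v.name, sign=sign)
        return g

    # -- compiled evaluation (lookup tables) ---------------------------------

    @property
    def compiled(self) -> "CompiledModel":
        """Lookup-table form of the image function (built lazily, cached)."""
        cached = getattr(self, "_compiled", None)
        if cached is None:
            cached = CompiledModel(self)
            self._compiled = cached
        return cached

    # -- dunder helpers -------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicalModel):
            return NotImplemented
        return (
            self.components == other.components
            and set(self.rules) == set(other.rules)
            and self.clamps == other.clamps
        )

    def __repr__(self) -> str:
        return (
            f"<LogicalModel {self.name or '(unnamed)'}: "
            f"{len(self.components)} components, {len(self.rules)} rules"
            + (f", {len(self.clamps)} clamps>" if self.clamps else ">")
        )


class CompiledModel:
    """Per-component image lookup tables for fast dynamics.

    For each non-input component the table maps the mixed-radix code of its
    regulators' levels to the clamped image.  Building the tables also
    re-checks rule exclusivity (an :class:`ExclusivityError` propagates).
    """

    def __init__(self, model: LogicalModel) -> None:
        self.model = model
        self.names = model.names
        self.index = {n: i for i, n in enumerate(self.names)}
        self.n = len(self.names)
        self.maxes = tuple(c.max_level for c in model.components)
        self.windows = tuple(model.clamp_window(n) for n in self.names)
        self.is_input = tuple(c.kind == "input" for c in model.components)
        self.reg_idx: list[tuple[int, ...]] = []
        self.tables: list[tuple[int, ...] | None] = []
        for c in model.components:
            if c.kind == "input":
                self.reg_idx.append(())
                self.tables.append(None)
                continue
            regs = model.regulators(c.name)
            self.reg_idx.append(tuple(self.index[r] for r in regs))
            ranges = [range(model.max_level(r) + 1) for r in regs]
            lo, hi = model.clamp_window(c.name)
            table = []
            for combo in itertools.product(*ranges):
                local = dict(zip(regs, combo))
                raw = model.raw_image(local, c.name)
                table.append(min(max(raw, lo), hi))
            self.tables.append(tuple(table))
        # dependents[i]: indices whose image depends on component i
        deps: list[set[int]] = [set() for _ in range(self.n)]
        for j, regs in enumerate(self.reg_idx):
            for r in regs:
                deps[r].add(j)
        self.dependents = tuple(tuple(sorted(d)) for d in deps)

    def target(self, state: Sequence[int], i: int) -> int:
        """Clamped image of component ``i`` at ``state`` (level sequence)."""
        if self.is_input[i]:
            lo, hi = self.windows[i]
            return min(max(state[i], lo), hi)
        code = 0
        for r in self.reg_idx[i]:
            code = code * (self.maxes[r] + 1) + state[r]
        return self.tables[i][code]

    def targets(self, state: Sequence[int]) -> list[int]:
        return [self.target(state, i) for i in range(self.n)]

    def state_tuple(self, state: State) -> tuple[int, ...]:
        return tuple(int(state[n]) for n in self.names)

    def state_dict(self, state: Sequence[int]) -> dict[str, int]:
        return dict(zip(self.names, state))
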