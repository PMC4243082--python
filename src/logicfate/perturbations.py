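"""Loss/gain-of-function perturbations and the systematic mutant screen.

A perturbation clamps one or more components into a level interval:
loss-of-function (LoF) is the interval ``[0, 0]``, gain-of-function (GoF)
any interval with a positive lower bound (a single positive level, or a
window such as ``[1, 2]`` for a component held positive but still
responsive within the window).  Applying a perturbation returns a new
model; the original is untouched.

The screen recomputes the stable states and fates of a perturbed model for
every damage condition and annotates the change against the wild type with
a small deterministic vocabulary:

* ``loss of F`` — fate F occurs under some wild-type condition but under no
  mutant condition;
* ``F enhanced`` — F occurs under strictly more conditions in the mutant;
* ``similar to the wild type`` — the fate maps are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import LogicalModel, ModelError
from .dynamics import stable_states
from .g1s import DAMAGE_CONDITIONS, FATE_NODES, fate_of

__all__ = [
    "Perturbation",
    "ScreenResult",
    "loss_of_function",
    "gain_of_function",
    "apply_perturbation",
    "mutant_screen",
    "outcome_changes",
    "screen_frame",
]


@dataclass(frozen=True)
class Perturbation:
    """One or more component clamps with a human-readable label."""

    targets: tuple[tuple[str, int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.targets:
            raise ModelError("a perturbation needs at least one target")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        parts = []
        for name, lo, hi in self.targets:
            if (lo, hi) == (0, 0):
                parts.append(f"{name} LoF")
            elif lo == hi:
                parts.append(f"{name} GoF[{lo}]")
            else:
                parts.append(f"{name} GoF[{lo},{hi}]")
        return " & ".join(parts)

    def clamps(self) -> dict[str, tuple[int, int]]:
        return {name: (lo, hi) for name, lo, hi in self.targets}


def loss_of_function(*names: str) -> Perturbation:
    return Perturbation(tuple((n, 0, 0) for n in names))


def gain_of_function(name: str, lo: int, hi: int | None = None) -> Perturbation:
    hi = lo if hi is None else hi
    if lo < 1:
        raise ModelError("gain of function requires a positive lower bound")
    return Perturbation(((name, lo, hi),))


def apply_perturbation(model: LogicalModel, perturbation: Perturbation) -> LogicalModel:
    """A copy of the model with the perturbation's clamps added."""
    for name, lo, hi in perturbation.targets:
        mx = model.max_level(name)  # raises on unknown component
        if not (0 <= lo <= hi <= mx):
            raise ModelError(
                f"perturbation {perturbation.label!r}: interval [{lo},{hi}] "
                f"outside [0,{mx}] for {name!r}"
            )
    return model.with_clamps(perturbation.clamps())


@dataclass(frozen=True)
class ScreenResult:
    """Stable states, fates, and wild-type comparison for one perturbation."""

    label: str
    perturbation: Perturbation
    #: condition -> tuple of stable states (each a name->level dict)
    states: dict[tuple[int, int], tuple[dict[str, int], ...]]
    #: condition -> tuple of fate sets, aligned with ``states``
    fates: dict[tuple[int, int], tuple[frozenset[str], ...]]
    annotations: frozenset[str]

    def fates_at(self, condition: tuple[int, int]) -> tuple[frozenset[str], ...]:
        return self.fates[condition]

    def fate_occurs(self, fate: str, condition: tuple[int, int]) -> bool:
        return any(fate in f for f in self.fates[condition])

    def conditions_with(self, fate: str) -> tuple[tuple[int, int], ...]:
        return tuple(c for c in self.fates if self.fate_occurs(fate, c))


def _fate_map(
    model: LogicalModel, conditions: Sequence[tuple[int, int]]
) -> tuple[dict, dict]:
    states_by_cond = {}
    fates_by_cond = {}
    for ssb, dsb in conditions:
        sts = stable_states(model, {"SSB": ssb, "DSB": dsb})
        states_by_cond[(ssb, dsb)] = tuple(sts)
        fates_by_cond[(ssb, dsb)] = tuple(fate_of(model, s) for s in sts)
    return states_by_cond, fates_by_cond


def outcome_changes(
    mutant_fates: Mapping[tuple[int, int], tuple[frozenset[str], ...]],
    wild_type_fates: Mapping[tuple[int, int], tuple[frozenset[str], ...]],
    fate_nodes: Sequence[str] = FATE_NODES,
) -> frozenset[str]:
    """Deterministic change annotations between two fate maps."""
    if set(mutant_fates) != set(wild_type_fates):
        raise ModelError("fate maps cover different condition sets")

    def occurs(fates, fate, cond):
        return any(fate in f for f in fates[cond])

    annotations = set()
    for fate in fate_nodes:
        wt_conds = {c for c in wild_type_fates if occurs(wild_type_fates, fate, c)}
        mu_conds = {c for c in mutant_fates if occurs(mutant_fates, fate, c)}
        if wt_conds and not mu_conds:
            annotations.add(f"loss of {fate}")
        if len(mu_conds) > len(wt_conds):
            annotations.add(f"{fate} enhanced")
    if all(
        set(mutant_fates[c]) == set(wild_type_fates[c]) for c in wild_type_fates
    ):
        annotations.add("similar to the wild type")
    return frozenset(annotations)


def mutant_screen(
    model: LogicalModel,
    perturbations: Iterable[Perturbation],
    conditions: Sequence[tuple[int, int]] = DAMAGE_CONDITIONS,
) -> list[ScreenResult]:
    """Run every perturbation over every damage condition.

    The wild-type fate map (the unperturbed ``model``) is computed once and
    every mutant is annotated against it.
    """
    _wt_states, wt_fates = _fate_map(model, conditions)
    results = []
    for pert in perturbations:
        mutant = apply_perturbation(model, pert)
        states, fates = _fate_map(mutant, conditions)
        results.append(
            ScreenResult(
                label=pert.label,
                perturbation=pert,
                states=states,
                fates=fates,
                annotations=outcome_changes(fates, wt_fates),
            )
        )
    return results


def screen_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Screen report: one row per perturbation x condition x stable state."""
    records = []
    for res in results:
        for (ssb, dsb), fates in sorted(res.fates.items()):
            for k, fate in enumerate(fates):
                records.append(
                    {
                        "perturbation": res.label,
                        "SSB": ssb,
                        "DSB": dsb,
                        "stable_state": k,
                        "n_stable_states": len(fates),
                        "fate": "+".join(sorted(fate)) if fate else "(none)",
                        "annotations": "; ".join(sorted(res.annotations)),
                    }
                )
    return pd.DataFrame.from_records(records)
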