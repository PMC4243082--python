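"""The G1/S DNA-damage-checkpoint model and its wild-type fate table.

The network links two graded damage inputs — single-strand breaks (SSB) and
double-strand breaks (DSB), each 0 (none), 1 (reparable) or 2 (irreparable)
— through the ATM/ATR kinase cascade, the stress kinase p38MAPK, the
p53–Mdm2 module and the p16INK4a/RB1 axis, to four Boolean cell-fate
read-outs: proliferation, cycle_arrest (transient arrest for repair),
senescence (permanent arrest) and apoptosis.

Every combination of damage levels drives the wild-type model to a single
stable state whose output values name the adopted fate: no damage gives
proliferation; irreparable DSB with sub-maximal SSB gives senescence (with
arrest); doubly irreparable damage gives apoptosis (with arrest); every
other combination gives transient cycle arrest.

One departure from a printed source rule is deliberate: p14ARF here
requires the *maximal* p38MAPK level (3) or E2F, not level 2.  With the
level-2 threshold, irreparable DSB alone would sequester Mdm2 via p14ARF,
drive p53 to its apoptotic level, and abolish the senescent outcome
entirely — contradicting the model's own reported fate map.  The level-3
threshold uniquely restores that map and parallels the p16INK4a rule
("2: p38MAPK = 3").  The alternative encoding remains available via
``build_g1s_model(variant="printed-p14ARF")``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import Component, LogicalModel, ModelError, Rule
from .dynamics import stable_states
from .io import column_order, parse_condition

__all__ = [
    "FATE_NODES",
    "DAMAGE_CONDITIONS",
    "build_g1s_model",
    "fate_of",
    "wild_type_fate_table",
    "fate_table",
    "fate_table_frame",
]

FATE_NODES = ("proliferation", "apoptosis", "senescence", "cycle_arrest")

#: the nine damage conditions (ssb, dsb), row order of the fate table
DAMAGE_CONDITIONS = tuple((ssb, dsb) for ssb in range(3) for dsb in range(3))

# name, max_level, kind — canonical component order (inputs, signalling
# cascade, core modules, cell-cycle drivers, fate read-outs)
_COMPONENTS = (
    ("SSB", 2, "input"),
    ("DSB", 2, "input"),
    ("ATM", 2, "internal"),
    ("ATR", 2, "internal"),
    ("CHEK1", 1, "internal"),
    ("CHEK2", 1, "internal"),
    ("p38MAPK", 3, "internal"),
    ("p14ARF", 1, "internal"),
    ("p16INK4a", 2, "internal"),
    ("Mdm2", 1, "internal"),
    ("p53", 2, "internal"),
    ("p21", 1, "internal"),
    ("CDC25A", 2, "internal"),
    ("E2F", 1, "internal"),
    ("RB1", 1, "internal"),
    ("CDK46CycD", 1, "internal"),
    ("CDK2CycE", 1, "internal"),
    ("proliferation", 1, "output"),
    ("apoptosis", 1, "output"),
    ("senescence", 1, "output"),
    ("cycle_arrest", 1, "output"),
)

# Rules under the threshold atom semantics ("X = n" reads X >= n; explicit
# ranges "a-b" are closed intervals).  Level-1 conditions of the graded
# sensors carry an explicit exclusion of the level-2 condition so that the
# rules of one component are mutually exclusive.
_RULES = (
    ("ATM", 1, "DSB = 1 AND NOT (DSB = 2)"),
    ("ATM", 2, "DSB = 2"),
    ("ATR", 1, "SSB = 1 AND NOT (SSB = 2)"),
    ("ATR", 2, "SSB = 2"),
    ("CHEK2", 1, "ATM = 2"),
    ("CHEK1", 1, "ATR = 2 OR ATM = 2"),
    ("p38MAPK", 1, "(ATM = 1 OR ATR = 1-2) AND NOT (ATM = 2)"),
    ("p38MAPK", 2, "ATM = 2 AND NOT (ATR = 2)"),
    ("p38MAPK", 3, "ATM = 2 AND ATR = 2"),
    ("p14ARF", 1, "p38MAPK = 3 OR E2F = 1"),
    ("p16INK4a", 1, "p38MAPK = 1-2"),
    ("p16INK4a", 2, "p38MAPK = 3"),
    ("Mdm2", 1, "p53 = 1 AND NOT (p14ARF = 1)"),
    ("p53", 1, "Mdm2 = 1 AND (p38MAPK = 3 OR ATR = 1-2 OR ATM = 1-2 "
               "OR CHEK1 = 1 OR CHEK2 = 1)"),
    ("p53", 2, "NOT (Mdm2 = 1) AND (p38MAPK = 3 OR ATR = 1-2 OR ATM = 1-2 "
               "OR CHEK1 = 1 OR CHEK2 = 1)"),
    ("p21", 1, "p53 = 1"),
    ("CDC25A", 1, "(p38MAPK = 1-3 OR CHEK2 = 1 OR CHEK1 = 1) "
                  "AND NOT (p38MAPK = 1-3 AND CHEK2 = 1 AND CHEK1 = 1)"),
    ("CDC25A", 2, "NOT (p38MAPK = 1-3) AND NOT (CHEK2 = 1) AND NOT (CHEK1 = 1)"),
    ("E2F", 1, "NOT (RB1 = 1)"),
    ("RB1", 1, "NOT (CDK46CycD = 1) AND NOT (CDK2CycE = 1)"),
    ("CDK46CycD", 1, "CDC25A = 1 AND NOT (p16INK4a = 1-2) AND NOT (p21 = 1)"),
    ("CDK2CycE", 1, "NOT (p21 = 1) AND CDC25A = 2 AND E2F = 1"),
    ("proliferation", 1, "CDK2CycE = 1"),
    ("apoptosis", 1, "p53 = 2"),
    ("senescence", 1, "(p16INK4a = 1 AND p21 = 1 AND NOT (CDC25A = 1-2) "
                      "AND NOT (p53 = 2)) OR (p16INK4a = 2 AND p21 = 1 "
                      "AND NOT (CDC25A = 2) AND NOT (p53 = 2))"),
    ("cycle_arrest", 1, "NOT (CDK2CycE = 1)"),
)

# Printed-source alternative for the p14ARF activation threshold; kept for
# inspection — it does NOT reproduce the wild-type fate map (see module
# docstring).
_P14ARF_PRINTED = ("p14ARF", 1, "p38MAPK = 2 OR E2F = 1")


def build_g1s_model(variant: str = "default") -> LogicalModel:
    """Construct the 21-component G1/S checkpoint model.

    Parameters
    ----------
    variant
        ``"default"`` uses the corrected p14ARF threshold (p38MAPK = 3);
        ``"printed-p14ARF"`` uses the level-2 threshold as printed in the
        source table, retained for comparison only.
    """
    if variant not in ("default", "printed-p14ARF"):
        raise ModelError(f"unknown G1/S variant {variant!r}")
    components = [Component(n, m, k) for n, m, k in _COMPONENTS]
    max_levels = {c.name: c.max_level for c in components}
    rule_rows = list(_RULES)
    if variant == "printed-p14ARF":
        rule_rows = [
            _P14ARF_PRINTED if (c, t) == ("p14ARF", 1) else (c, t, expr)
            for c, t, expr in rule_rows
        ]
    rules = [
        Rule(comp, target, parse_condition(expr, max_levels))
        for comp, target, expr in rule_rows
    ]
    model = LogicalModel(
        components,
        rules,
        name="G1S-checkpoint" if variant == "default" else f"G1S-checkpoint[{variant}]",
        metadata={
            "description": "G1/S DNA-damage checkpoint cell-fate decision model",
            "p14ARF_variant": variant,
            "naming": "canonical spellings: cycle_arrest, CDK46CycD, CDK2CycE",
        },
    )
    return model


def fate_of(model: LogicalModel, state: Mapping[str, int]) -> frozenset[str]:
    """Cell fate of a stable state: the set of output nodes at level 1.

    Raises :class:`ModelError` if ``state`` is not a fixed point — fates
    are read-outs of attractors, not of transient states.
    """
    if not model.is_stable(state):
        raise ModelError("fate is only defined at a stable state")
    outputs = [c.name for c in model.components if c.kind == "output"]
    return frozenset(n for n in outputs if state[n] == 1)


@dataclass(frozen=True)
class FateRow:
    """One damage condition of a fate table: its stable states and fates."""

    ssb: int
    dsb: int
    states: tuple[dict[str, int], ...]
    fates: tuple[frozenset[str], ...]


def fate_table(model: LogicalModel) -> list[FateRow]:
    """Stable states and fates for all nine (SSB, DSB) damage conditions."""
    rows = []
    for ssb, dsb in DAMAGE_CONDITIONS:
        states = stable_states(model, {"SSB": ssb, "DSB": dsb})
        ordered = sorted(states, key=lambda s: tuple(s[n] for n in model.names))
        fates = tuple(fate_of(model, s) for s in ordered)
        rows.append(FateRow(ssb, dsb, tuple(ordered), fates))
    return rows


def wild_type_fate_table(variant: str = "default") -> list[FateRow]:
    """The wild-type fate table: one stable state per damage condition."""
    return fate_table(build_g1s_model(variant))


def fate_table_frame(model: LogicalModel, rows: list[FateRow] | None = None) -> pd.DataFrame:
    """Fate table as a DataFrame (one stable state per row, fate column last)."""
    if rows is None:
        rows = fate_table(model)
    cols = column_order(model)
    records = []
    for row in rows:
        for state, fates in zip(row.states, row.fates):
            rec = {c: state[c] for c in cols}
            rec["fate"] = "+".join(sorted(fates)) if fates else "(none)"
            records.append(rec)
    return pd.DataFrame(records, columns=cols + ["fate"])
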