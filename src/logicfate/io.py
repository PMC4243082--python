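"""Model file format, rule-expression grammar, and tabular report writers.

Model files are JSON with a small fixed schema::

    {
      "format": "logicfate-model/1",
      "name": "...",
      "metadata": {...},                     # free-form provenance notes
      "components": [
        {"name": "SSB", "max_level": 2, "kind": "input"}, ...
      ],
      "rules": [
        {"component": "ATM", "target": 2, "condition": "DSB = 2"}, ...
      ],
      "clamps": {"p16INK4a": [1, 2]}         # optional
    }

Rule conditions are strings over a small grammar:

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := NOT factor | '(' expr ')' | atom
    atom   := NAME | NAME '=' INT | NAME '=' INT '-' INT | NAME '>=' INT

Atom semantics follow the threshold convention of multi-valued logical
modelling: a bare ``X = n`` means *level n or above* (interval
``[n, max(X)]``); an explicit range ``X = a-b`` means ``[a, b]``;
``X >= n`` is an explicit synonym of the threshold form; a bare name is
shorthand for ``X >= 1``.  Where a rule needs an exact level below the
maximum it is written with an explicit range or an explicit exclusion
(``X = 1 AND NOT (X = 2)``), mirroring how such rules are written in the
logical-modelling literature.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import And, Atom, Component, Condition, LogicalModel, ModelError, Not, Or, Rule

__all__ = [
    "parse_condition",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
    "states_frame",
    "ParseError",
]

FORMAT_TAG = "logicfate-model/1"


class ParseError(ModelError):
    """A rule expression or model file that does not match the grammar."""


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<ge>>=)|(?P<eq>=)|(?P<dash>-)"
    r"|(?P<int>\d+)|(?P<word>[A-Za-z_][A-Za-z0-9_]*))"
)
_KEYWORDS = {"AND", "OR", "NOT"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ParseError(f"unexpected character {rest[0]!r} in rule: {text!r}")
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "word" and value.upper() in _KEYWORDS:
            tokens.append((value.upper(), value))
        else:
            tokens.append((kind, value))
    return tokens


class _Parser:
    def __init__(self, text: str, max_levels: Mapping[str, int]) -> None:
        self.text = text
        self.max_levels = max_levels
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        if self.pos >= len(self.tokens):
            raise ParseError(f"unexpected end of rule: {self.text!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str) -> str:
        k, v = self.next()
        if k != kind:
            raise ParseError(f"expected {kind} but found {v!r} in rule: {self.text!r}")
        return v

    def parse(self) -> Condition:
        cond = self.expr()
        if self.pos != len(self.tokens):
            extra = self.tokens[self.pos][1]
            raise ParseError(f"trailing input {extra!r} in rule: {self.text!r}")
        return cond

    def expr(self) -> Condition:
        terms = [self.term()]
        while self.peek() == "OR":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def term(self) -> Condition:
        factors = [self.factor()]
        while self.peek() == "AND":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(*factors)

    def factor(self) -> Condition:
        kind = self.peek()
        if kind == "NOT":
            self.next()
            return Not(self.factor())
        if kind == "lparen":
            self.next()
            cond = self.expr()
            self.expect("rparen")
            return cond
        return self.atom()

    def atom(self) -> Condition:
        name = self.expect("word")
        if name not in self.max_levels:
            raise ParseError(f"unknown component {name!r} in rule: {self.text!r}")
        mx = self.max_levels[name]
        kind = self.peek()
        if kind == "ge":
            self.next()
            lo = int(self.expect("int"))
            return self._atom(name, lo, mx, mx)
        if kind == "eq":
            self.next()
            lo = int(self.expect("int"))
            if self.peek() == "dash":
                self.next()
                hi = int(self.expect("int"))
                return self._atom(name, lo, hi, mx)
            # threshold convention: bare "X = n" reads as X >= n
            return self._atom(name, lo, mx, mx)
        # bare name: Boolean shorthand for X >= 1
        return self._atom(name, 1, mx, mx)

    def _atom(self, name: str, lo: int, hi: int, mx: int) -> Atom:
        if not (0 <= lo <= hi <= mx):
            raise ParseError(
                f"atom {name} = {lo}-{hi} outside level range [0,{mx}] "
                f"in rule: {self.text!r}"
            )
        return Atom(name, lo, hi)


def parse_condition(text: str, max_levels: Mapping[str, int]) -> Condition:
    """Parse a rule-condition string under the threshold atom semantics."""
    return _Parser(text, max_levels).parse()


# ---------------------------------------------------------------------------
# model (de)serialisation


def model_to_dict(model: LogicalModel) -> dict:
    """Canonical JSON-ready form of a model (conditions as range strings)."""
    return {
        "format": FORMAT_TAG,
        "name": model.name,
        "metadata": model.metadata,
        "components": [
            {"name": c.name, "max_level": c.max_level, "kind": c.kind}
            for c in model.components
        ],
        "rules": [
            {
                "component": r.component,
                "target": r.target_level,
                "condition": r.condition.to_string(),
            }
            for r in model.rules
        ],
        "clamps": {k: list(v) for k, v in sorted(model.clamps.items())},
    }


def _require(cond: bool, where: str, message: str) -> None:
    if not cond:
        raise ParseError(f"model file, {where}: {message}")


def model_from_dict(data: dict, validate: bool = True) -> LogicalModel:
    """Build and (by default) validate a model from its dict form."""
    _require(isinstance(data, dict), "top level", "expected a JSON object")
    _require(
        data.get("format") == FORMAT_TAG,
        "top level",
        f"format must be {FORMAT_TAG!r}, found {data.get('format')!r}",
    )
    raw_components = data.get("components")
    _require(
        isinstance(raw_components, list) and raw_components,
        "components",
        "expected a non-empty list",
    )
    components = []
    for i, c in enumerate(raw_components):
        where = f"components[{i}]"
        _require(isinstance(c, dict), where, "expected an object")
        _require(isinstance(c.get("name"), str), where, "missing string 'name'")
        _require(
            isinstance(c.get("max_level", 1), int), where, "'max_level' must be an integer"
        )
        components.append(
            Component(
                name=c["name"],
                max_level=c.get("max_level", 1),
                kind=c.get("kind", "internal"),
            )
        )
    max_levels = {c.name: c.max_level for c in components}
    rules = []
    for i, r in enumerate(data.get("rules", [])):
        where = f"rules[{i}]"
        _require(isinstance(r, dict), where, "expected an object")
        for key in ("component", "target", "condition"):
            _require(key in r, where, f"missing field {key!r}")
        _require(
            r["component"] in max_levels,
            where,
            f"unknown component {r['component']!r}",
        )
        try:
            cond = parse_condition(r["condition"], max_levels)
        except ParseError as exc:
            raise ParseError(f"model file, {where}: {exc}") from None
        rules.append(Rule(r["component"], int(r["target"]), cond))
    clamps = {}
    for name, interval in (data.get("clamps") or {}).items():
        where = f"clamps[{name!r}]"
        _require(name in max_levels, where, "unknown component")
        _require(
            isinstance(interval, (list, tuple)) and len(interval) == 2,
            where,
            "expected [lo, hi]",
        )
        clamps[name] = (int(interval[0]), int(interval[1]))
    model = LogicalModel(
        components,
        rules,
        clamps,
        name=data.get("name", ""),
        metadata=data.get("metadata"),
    )
    if validate:
        violations = model.validate()
        if violations:
            detail = "; ".join(str(v) for v in violations)
            raise ModelError(f"model file fails validation: {detail}")
    return model


def read_model(path: str | Path, validate: bool = True) -> LogicalModel:
    """Read, parse and validate a model file; fails loudly on violations."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON ({exc})") from None
    return model_from_dict(data, validate=validate)


def write_model(model: LogicalModel, path: str | Path) -> None:
    """Serialise a model to its canonical JSON form (read∘write = identity)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# tabular output


def column_order(model: LogicalModel) -> list[str]:
    """Canonical column order for state tables: outputs, internals, inputs.

    Mirrors the usual stable-state figure layout (cell-fate read-outs in the
    left-most columns, damage inputs in the right-most), easing visual
    comparison of wild-type tables.
    """
    outputs = [c.name for c in model.components if c.kind == "output"]
    internals = [c.name for c in model.components if c.kind == "internal"]
    inputs = [c.name for c in model.components if c.kind == "input"]
    return outputs + internals + inputs


def states_frame(model: LogicalModel, states: list[Mapping[str, int]]) -> pd.DataFrame:
    """States as a DataFrame, one row per state, canonically ordered."""
    cols = column_order(model)
    rows = sorted(
        (tuple(int(s[c]) for c in cols) for s in states),
    )
    return pd.DataFrame(rows, columns=cols, dtype=int)
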