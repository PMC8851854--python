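"""KEGG module DEFINITION parsing and completeness calling.

A KEGG module describes a pathway unit as an ordered list of *steps*, each a
boolean expression over KO gene-family identifiers: at the top level,
space-separated units are successive steps; within a step, ``,`` is OR
(alternative orthologs), ``+`` is AND (subunits of a complex), a ``-``-prefixed
component is optional (non-essential), parentheses group, and a bare ``--``
marks a gap step that carries no gene requirement and is excluded from the
step count.  Module completeness is the fraction of counted steps whose
expression is satisfied by the KOs present in a genome; a module is called
present when completeness reaches a configurable cutoff (default 75%).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError, ParseError

DEFAULT_MODULE_CUTOFF = 0.75

_KO_RE = re.compile(r"K\d{5}$")
_MODULE_RE = re.compile(r"M\d{5}$")
_TOKEN_RE = re.compile(r"K\d{5}|M\d{5}|--|[(),+\- ]")


# AST: ("ko", id) | ("module", id) | ("and", [children]) | ("or", [children])
#      | ("opt", child) | ("gap",)
Expr = tuple


class _Parser:
    """Recursive-descent parser for one DEFINITION string.

    Precedence, loosest to tightest: space (AND between steps/sub-steps),
    comma (OR), plus/minus (AND chain with optional components).
    """

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        i = 0
        while i < len(text):
            m = _TOKEN_RE.match(text, i)
            if m is None:
                raise ParseError(f"illegal token at position {i}: {text[i:i + 8]!r}")
            tok = m.group(0)
            if tok != " ":
                self.tokens.append((tok, i))
            else:
                self.tokens.append((" ", i))
            i = m.end()
        self.idx = 0

    def _peek(self) -> str | None:
        return self.tokens[self.idx][0] if self.idx < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self.tokens[self.idx]
        self.idx += 1
        return tok

    def parse_expr(self) -> Expr:
        parts = [self.parse_or()]
        while self._peek() == " ":
            self._next()
            if self._peek() in (None, ")"):
                break
            parts.append(self.parse_or())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_or(self) -> Expr:
        parts = [self.parse_and()]
        while self._peek() == ",":
            self._next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def parse_and(self) -> Expr:
        parts: list[Expr] = []
        if self._peek() == "-":  # leading optional component
            self._next()
            parts.append(("opt", self.parse_unit()))
        else:
            parts.append(self.parse_unit())
        while self._peek() in ("+", "-"):
            op, _ = self._next()
            unit = self.parse_unit()
            parts.append(("opt", unit) if op == "-" else unit)
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_unit(self) -> Expr:
        tok = self._peek()
        if tok is None:
            raise ParseError(f"unexpected end of definition at position {len(self.text)}")
        tok, pos = self._next()
        if tok == "(":
            inner = self.parse_expr()
            if self._peek() != ")":
                raise ParseError(f"unbalanced parenthesis opened at position {pos}")
            self._next()
            return inner
        if _KO_RE.match(tok):
            return ("ko", tok)
        if _MODULE_RE.match(tok):
            return ("module", tok)
        raise ParseError(f"unexpected token {tok!r} at position {pos}")


@dataclass(frozen=True)
class ModuleDefinition:
    """Parsed module: ordered steps, with gap ('--') steps flagged."""

    module_id: str
    steps: tuple[Expr, ...]          # counted steps only
    n_gaps: int = 0
    definition: str = ""
    name: str = ""

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class ModuleCall:
    """Completeness of one module against a KO presence set."""

    module_id: str
    n_steps: int
    n_present: int
    completeness: float
    step_states: tuple[bool, ...]
    present: bool | None = None
    cutoff: float | None = None


def _split_top_level(text: str) -> list[str]:
    """Split on spaces not enclosed in parentheses."""
    units, depth, cur = [], 0, []
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced parenthesis at position {i}")
        if ch == " " and depth == 0:
            if cur:
                units.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise ParseError("unbalanced parentheses")
    if cur:
        units.append("".join(cur))
    return units


def parse_definition(text: str, module_id: str = "", name: str = "") -> ModuleDefinition:
    """Parse a DEFINITION string into an ordered step list."""
    text = text.strip()
    if not text:
        raise ParseError("empty definition")
    steps: list[Expr] = []
    n_gaps = 0
    for unit in _split_top_level(text):
        if unit == "--":
            n_gaps += 1
            continue
        parser = _Parser(unit)
        expr = parser.parse_expr()
        if parser.idx != len(parser.tokens):
            tok, pos = parser.tokens[parser.idx]
            raise ParseError(f"unexpected token {tok!r} at position {pos}")
        steps.append(expr)
    if not steps:
        raise ParseError("definition has no counted steps")
    return ModuleDefinition(module_id=module_id, steps=tuple(steps), n_gaps=n_gaps,
                            definition=text, name=name)


def evaluate_expr(expr: Expr, present_kos: frozenset[str] | set[str],
                  module_memo: Mapping[str, bool] | None = None) -> bool:
    """Evaluate one step expression; optional components are vacuously true."""
    kind = expr[0]
    if kind == "ko":
        return expr[1] in present_kos
    if kind == "module":
        return bool(module_memo.get(expr[1], False)) if module_memo else False
    if kind == "opt":
        return True
    if kind == "and":
        return all(evaluate_expr(c, present_kos, module_memo) for c in expr[1])
    if kind == "or":
        return any(evaluate_expr(c, present_kos, module_memo) for c in expr[1])
    raise ConfigError(f"unknown expression node {kind!r}")


def module_completeness(defn: ModuleDefinition, present_kos: set[str] | frozenset[str],
                        module_memo: Mapping[str, bool] | None = None) -> ModuleCall:
    """Fraction of counted steps satisfied by the present KO set."""
    states = tuple(evaluate_expr(s, present_kos, module_memo) for s in defn.steps)
    n_present = sum(states)
    return ModuleCall(
        module_id=defn.module_id,
        n_steps=defn.n_steps,
        n_present=n_present,
        completeness=n_present / defn.n_steps,
        step_states=states,
    )


def call_presence(call: ModuleCall, cutoff: float = DEFAULT_MODULE_CUTOFF) -> ModuleCall:
    """Call a module present when completeness >= cutoff (default 0.75)."""
    if not 0 < cutoff <= 1:
        raise ConfigError(f"module cutoff must be in (0, 1], got {cutoff}")
    return ModuleCall(
        module_id=call.module_id,
        n_steps=call.n_steps,
        n_present=call.n_present,
        completeness=call.completeness,
        step_states=call.step_states,
        present=call.completeness >= cutoff,
        cutoff=cutoff,
    )
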