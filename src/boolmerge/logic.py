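"""Boolean expression trees for logical-model rules.

Rules are propositional formulas over gene/protein identifiers with three
operators: negation ``!``, conjunction ``&`` and disjunction ``|``
(precedence ``!`` > ``&`` > ``|``, left-associative, parentheses override).
Constants ``0``/``1`` are admitted so clamped (mutated) nodes are
expressible.  Identifiers are case-sensitive tokens ``[A-Za-z0-9_]+``.

Regulator signs (activator / inhibitor / dual) are inferred semantically by
an exhaustive flip test by default, with a syntactic negation-parity
fallback for expressions whose support exceeds the exhaustive cap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BoolExpr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "SignedInfluence",
    "RuleSyntaxError",
    "MissingVariableError",
    "SupportCapError",
    "parse_rule",
    "to_text",
    "evaluate",
    "variables",
    "support",
    "infer_signs",
    "syntactic_signs",
    "exprs_equivalent",
    "conj",
    "disj",
    "negate",
    "substitute",
]

_IDENT_RE = re.compile(r"[A-Za-z0-9_]+")

SIGN_ACTIVATOR = "activator"
SIGN_INHIBITOR = "inhibitor"
SIGN_DUAL = "dual"
SIGN_NONE = "none"


class BoolExpr:
    """Base class for Boolean expression nodes."""

    __slots__ = ()

    def __call__(self, state: Mapping[str, int]) -> int:
        return evaluate(self, state)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return to_text(self)


@dataclass(frozen=True, repr=False)
class Var(BoolExpr):
    """Reference to a node identifier."""

    name: str

    def __post_init__(self) -> None:
        if not _IDENT_RE.fullmatch(self.name):
            raise ValueError(f"invalid identifier: {self.name!r}")

    def __repr__(self) -> str:
        return f"Var({self.name})"


@dataclass(frozen=True, repr=False)
class Const(BoolExpr):
    """Constant 0 or 1 (used for clamped nodes)."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {self.value!r}")

    def __repr__(self) -> str:
        return f"Const({self.value})"


@dataclass(frozen=True, repr=False)
class Not(BoolExpr):
    child: BoolExpr

    def __repr__(self) -> str:
        return f"Not({self.child!r})"


@dataclass(frozen=True, repr=False)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("And requires at least two children")
        if any(isinstance(c, And) for c in self.children):
            raise ValueError("And children must be flattened")

    def __repr__(self) -> str:
        return "And(" + ", ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True, repr=False)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("Or requires at least two children")
        if any(isinstance(c, Or) for c in self.children):
            raise ValueError("Or children must be flattened")

    def __repr__(self) -> str:
        return "Or(" + ", ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True)
class SignedInfluence:
    """A signed regulatory edge regulator -> target."""

    regulator: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in (SIGN_ACTIVATOR, SIGN_INHIBITOR, SIGN_DUAL, SIGN_NONE):
            raise ValueError(f"unknown sign {self.sign!r}")


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the character position of the error."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MissingVariableError(KeyError):
    """A rule was evaluated under a state missing one of its variables."""

    def __init__(self, name: str) -> None:
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:
        return f"no value assigned for variable {self.name!r}"


class SupportCapError(ValueError):
    """Exhaustive analysis requested on a support larger than the cap."""


# ---------------------------------------------------------------------------
# smart constructors (flattening, degenerate-arity collapse)


def conj(children: Iterable[BoolExpr]) -> BoolExpr:
    """AND of ``children``, flattening nested ANDs; unary collapses."""
    flat: list[BoolExpr] = []
    for c in children:
        if isinstance(c, And):
            flat.extend(c.children)
        else:
            flat.append(c)
    if not flat:
        return Const(1)
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


def disj(children: Iterable[BoolExpr]) -> BoolExpr:
    """OR of ``children``, flattening nested ORs; unary collapses."""
    flat: list[BoolExpr] = []
    for c in children:
        if isinstance(c, Or):
            flat.extend(c.children)
        else:
            flat.append(c)
    if not flat:
        return Const(0)
    if len(flat) == 1:
        return flat[0]
    return Or(tuple(flat))


def negate(expr: BoolExpr) -> BoolExpr:
    if isinstance(expr, Not):
        return expr.child
    if isinstance(expr, Const):
        return Const(1 - expr.value)
    return Not(expr)


# ---------------------------------------------------------------------------
# parsing / serialization


class _Parser:
    """Recursive-descent parser for the rule grammar.

    expr   := term  ('|' term)*
    term   := factor ('&' factor)*
    factor := '!' factor | '(' expr ')' | IDENT | '0' | '1'
    """

    _TOKEN_RE = re.compile(r"\s*(?:([A-Za-z0-9_]+)|([&|!()])|(\S))")

    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = self._TOKEN_RE.match(text, pos)
            if m is None:
                break
            if m.group(3):
                raise RuleSyntaxError(
                    f"unexpected character {m.group(3)!r}", m.start(3)
                )
            tok = m.group(1) or m.group(2)
            self.tokens.append((tok, m.start(1) if m.group(1) else m.start(2)))
            pos = m.end()
        self.idx = 0

    def _peek(self) -> str | None:
        return self.tokens[self.idx][0] if self.idx < len(self.tokens) else None

    def _pos(self) -> int:
        if self.idx < len(self.tokens):
            return self.tokens[self.idx][1]
        return len(self.text)

    def _advance(self) -> str:
        tok = self.tokens[self.idx][0]
        self.idx += 1
        return tok

    def parse(self) -> BoolExpr:
        if not self.tokens:
            raise RuleSyntaxError("empty rule", 0)
        expr = self._expr()
        if self.idx < len(self.tokens):
            raise RuleSyntaxError(
                f"unexpected token {self._peek()!r}", self._pos()
            )
        return expr

    def _expr(self) -> BoolExpr:
        terms = [self._term()]
        while self._peek() == "|":
            self._advance()
            terms.append(self._term())
        return disj(terms)

    def _term(self) -> BoolExpr:
        factors = [self._factor()]
        while self._peek() == "&":
            self._advance()
            factors.append(self._factor())
        return conj(factors)

    def _factor(self) -> BoolExpr:
        tok = self._peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of rule", self._pos())
        if tok == "!":
            self._advance()
            return negate(self._factor())
        if tok == "(":
            self._advance()
            inner = self._expr()
            if self._peek() != ")":
                raise RuleSyntaxError("expected ')'", self._pos())
            self._advance()
            return inner
        if tok in ("&", "|", ")"):
            raise RuleSyntaxError(f"unexpected token {tok!r}", self._pos())
        self._advance()
        if tok == "0":
            return Const(0)
        if tok == "1":
            return Const(1)
        return Var(tok)


def parse_rule(text: str) -> BoolExpr:
    """Parse rule text into a :class:`BoolExpr`.

    Raises :class:`RuleSyntaxError` (with position) on malformed or empty
    input.
    """
    if not isinstance(text, str) or not text.strip():
        raise RuleSyntaxError("empty rule", 0)
    return _Parser(text).parse()


def to_text(expr: BoolExpr) -> str:
    """Serialize with minimal parentheses under ``!`` > ``&`` > ``|``."""
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Not):
        inner = to_text(expr.child)
        if isinstance(expr.child, (And, Or)):
            return f"!({inner})"
        return f"!{inner}"
    if isinstance(expr, And):
        parts = [
            f"({to_text(c)})" if isinstance(c, Or) else to_text(c)
            for c in expr.children
        ]
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(to_text(c) for c in expr.children)
    raise TypeError(f"not a BoolExpr: {expr!r}")


# ---------------------------------------------------------------------------
# semantics


def evaluate(expr: BoolExpr, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a total assignment; returns 0 or 1."""
    if isinstance(expr, Var):
        try:
            return 1 if state[expr.name] else 0
        except KeyError:
            raise MissingVariableError(expr.name) from None
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - evaluate(expr.child, state)
    if isinstance(expr, And):
        for c in expr.children:
            if not evaluate(c, state):
                return 0
        return 1
    if isinstance(expr, Or):
        for c in expr.children:
            if evaluate(c, state):
                return 1
        return 0
    raise TypeError(f"not a BoolExpr: {expr!r}")


def variables(expr: BoolExpr) -> set[str]:
    """Identifiers appearing syntactically in ``expr``."""
    out: set[str] = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Var):
            out.add(e.name)
        elif isinstance(e, Not):
            stack.append(e.child)
        elif isinstance(e, (And, Or)):
            stack.extend(e.children)
    return out


def _assignments(names: Sequence[str]):
    for bits in product((0, 1), repeat=len(names)):
        yield dict(zip(names, bits))


def support(expr: BoolExpr, cap: int = 20) -> set[str]:
    """Semantic support: variables whose value can change the output.

    A variable is in the support iff some assignment exists where flipping
    it flips the output.  Absorbed or contradictory variables are excluded.
    """
    names = sorted(variables(expr))
    if len(names) > cap:
        raise SupportCapError(
            f"support of size {len(names)} exceeds exhaustive cap {cap}"
        )
    live: set[str] = set()
    for state in _assignments(names):
        base = evaluate(expr, state)
        for v in names:
            if v in live:
                continue
            state[v] ^= 1
            if evaluate(expr, state) != base:
                live.add(v)
            state[v] ^= 1
        if len(live) == len(names):
            break
    return live


def infer_signs(
    expr: BoolExpr, target: str, cap: int = 16
) -> list[SignedInfluence]:
    """Classify each syntactic regulator of ``target``'s rule by flip test.

    ``activator`` if raising the regulator can only raise the output,
    ``inhibitor`` if it can only lower it, ``dual`` if witnesses of both
    directions exist, ``none`` if the regulator never changes the output.
    Raises :class:`SupportCapError` above ``cap`` variables; use
    :func:`syntactic_signs` as the fallback there.
    """
    names = sorted(variables(expr))
    if len(names) > cap:
        raise SupportCapError(
            f"{len(names)} regulators exceed the exhaustive sign-inference "
            f"cap {cap}; use the syntactic fallback (syntactic_signs)"
        )
    up: set[str] = set()
    down: set[str] = set()
    for state in _assignments(names):
        for v in names:
            if v in up and v in down:
                continue
            if state[v] == 1:
                continue
            lo = evaluate(expr, state)
            state[v] = 1
            hi = evaluate(expr, state)
            state[v] = 0
            if lo == 0 and hi == 1:
                up.add(v)
            elif lo == 1 and hi == 0:
                down.add(v)
    out = []
    for v in names:
        if v in up and v in down:
            sign = SIGN_DUAL
        elif v in up:
            sign = SIGN_ACTIVATOR
        elif v in down:
            sign = SIGN_INHIBITOR
        else:
            sign = SIGN_NONE
        out.append(SignedInfluence(v, target, sign))
    return out


def syntactic_signs(expr: BoolExpr, target: str) -> list[SignedInfluence]:
    """Negation-parity sign classification (no exhaustive enumeration).

    A regulator is flagged inhibitor if any of its occurrences lies under an
    odd number of negations, activator for even parity, dual for both.
    """
    even: set[str] = set()
    odd: set[str] = set()

    def walk(e: BoolExpr, parity: int) -> None:
        if isinstance(e, Var):
            (odd if parity else even).add(e.name)
        elif isinstance(e, Not):
            walk(e.child, parity ^ 1)
        elif isinstance(e, (And, Or)):
            for c in e.children:
                walk(c, parity)

    walk(expr, 0)
    out = []
    for v in sorted(even | odd):
        if v in even and v in odd:
            sign = SIGN_DUAL
        elif v in odd:
            sign = SIGN_INHIBITOR
        else:
            sign = SIGN_ACTIVATOR
        out.append(SignedInfluence(v, target, sign))
    return out


def exprs_equivalent(a: BoolExpr, b: BoolExpr, cap: int = 20) -> bool:
    """True iff ``a`` and ``b`` agree on every assignment of their joint
    variables."""
    names = sorted(variables(a) | variables(b))
    if len(names) > cap:
        raise SupportCapError(
            f"joint support of size {len(names)} exceeds cap {cap}"
        )
    for state in _assignments(names):
        if evaluate(a, state) != evaluate(b, state):
            return False
    return True


def substitute(expr: BoolExpr, renames: Mapping[str, str]) -> BoolExpr:
    """Rename variables throughout ``expr``."""
    if isinstance(expr, Var):
        return Var(renames.get(expr.name, expr.name))
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(substitute(expr.child, renames))
    if isinstance(expr, And):
        return And(tuple(substitute(c, renames) for c in expr.children))
    if isinstance(expr, Or):
        return Or(tuple(substitute(c, renames) for c in expr.children))
    raise TypeError(f"not a BoolExpr: {expr!r}")
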