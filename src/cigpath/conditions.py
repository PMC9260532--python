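"""Three-valued condition logic for sequence-flow guards.

Edge conditions are evaluated against a treatment context under Kleene's
strong three-valued logic: a condition is satisfied (TRUE), unsatisfied
(FALSE) or cannot be decided with the data provided (UNKNOWN).  UNKNOWN
arises exactly when a referenced variable is absent from the context;
Kleene's connectives then propagate it unless dominated (FALSE dominates
``and``, TRUE dominates ``or``).

The expression language is deliberately small::

    expr      := or_expr
    or_expr   := and_expr ("or" and_expr)*
    and_expr  := not_expr ("and" not_expr)*
    not_expr  := "not" not_expr | comparison
    comparison:= operand (("==" | "!=" | "<" | "<=" | ">" | ">=") operand)?
    operand   := "true" | "false" | NUMBER | STRING | IDENT | "(" expr ")"

Identifiers name context variables.  Scalars are booleans, numbers or
strings; ordering comparisons are defined on numbers only, equality requires
operands of the same kind.  A comparison over *present* values of
incompatible kinds is a modeling error and raises, whereas an absent
variable yields UNKNOWN — the two situations are deliberately distinct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Union

from .errors import ContextError, EvaluationError, ExpressionSyntaxError

__all__ = [
    "TriState",
    "and3",
    "or3",
    "not3",
    "TreatmentContext",
    "ConditionExpr",
    "parse_expression",
    "evaluate",
    "resolve_criterion",
    "CriterionResolver",
]

Scalar = Union[bool, int, float, str]

_MAX_IDENT = 256


class TriState(Enum):
    """Kleene truth value, ordered FALSE < UNKNOWN < TRUE (information order
    used by the monotone fixpoints in :mod:`cigpath.contextualize`)."""

    FALSE = 0
    UNKNOWN = 1
    TRUE = 2

    @classmethod
    def of(cls, value: bool) -> "TriState":
        return cls.TRUE if value else cls.FALSE


def and3(*values: TriState) -> TriState:
    """Kleene conjunction: minimum in the order FALSE < UNKNOWN < TRUE."""
    result = TriState.TRUE
    for v in values:
        if v.value < result.value:
            result = v
    return result


def or3(*values: TriState) -> TriState:
    """Kleene disjunction: maximum in the order FALSE < UNKNOWN < TRUE."""
    result = TriState.FALSE
    for v in values:
        if v.value > result.value:
            result = v
    return result


def not3(value: TriState) -> TriState:
    if value == TriState.UNKNOWN:
        return TriState.UNKNOWN
    return TriState.FALSE if value == TriState.TRUE else TriState.TRUE


# --------------------------------------------------------------------------
# Treatment context
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentContext:
    """Patient-specific facts: which tasks were executed (with what recorded
    outcome) and the values of named variables.

    Every executed task's outcome is also visible as a variable named by the
    task id, unless shadowed by an explicitly supplied variable.  A name
    absent from the effective variable map means UNKNOWN.
    """

    executed: dict[str, Scalar] = field(default_factory=dict)
    variables: dict[str, Scalar] = field(default_factory=dict)

    def is_executed(self, task_id: str) -> bool:
        return task_id in self.executed

    def lookup(self, name: str) -> tuple[bool, Scalar | None]:
        """(present, value); explicit variables shadow executed outcomes."""
        if name in self.variables:
            return True, self.variables[name]
        if name in self.executed:
            return True, self.executed[name]
        return False, None

    @staticmethod
    def _check_scalar(name: str, value: object) -> Scalar:
        if isinstance(value, (bool, int, float, str)):
            return value
        raise ContextError(
            f"value for {name!r} must be a boolean, number or string, "
            f"got {type(value).__name__}")

    @classmethod
    def from_mappings(cls, executed: dict | None, variables: dict | None
                      ) -> "TreatmentContext":
        ex = {k: cls._check_scalar(k, v) for k, v in (executed or {}).items()}
        va = {k: cls._check_scalar(k, v) for k, v in (variables or {}).items()}
        return cls(executed=ex, variables=va)


# --------------------------------------------------------------------------
# Parse trees
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Literal:
    value: Scalar


@dataclass(frozen=True)
class VarRef:
    name: str


@dataclass(frozen=True)
class Comparison:
    op: str  # ==, !=, <, <=, >, >=
    left: "ConditionExpr"
    right: "ConditionExpr"


@dataclass(frozen=True)
class Not:
    operand: "ConditionExpr"


@dataclass(frozen=True)
class BoolOp:
    op: str  # and, or
    operands: tuple["ConditionExpr", ...]


ConditionExpr = Union[Literal, VarRef, Comparison, Not, BoolOp]


# --------------------------------------------------------------------------
# Tokenizer / recursive-descent parser
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<op>==|!=|<=|>=|<|>)
      | (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<number>-?\d+(?:\.\d+)?)
      | (?P<string>'[^']*'|"[^"]*")
      | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"true", "false", "not", "and", "or"}


@dataclass(frozen=True)
class _Token:
    kind: str
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.lastgroup is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            at = len(text) - len(stripped)
            raise ExpressionSyntaxError(
                f"unexpected character {stripped[0]!r}", at)
        kind = m.lastgroup
        tok_text = m.group(kind)
        tok_pos = m.end() - len(tok_text)
        if kind == "ident":
            if len(tok_text) > _MAX_IDENT:
                raise ExpressionSyntaxError(
                    f"identifier longer than {_MAX_IDENT} characters", tok_pos)
            if tok_text in _KEYWORDS:
                kind = tok_text
        tokens.append(_Token(kind, tok_text, tok_pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> _Token | None:
        tok = self._peek()
        if tok is not None:
            self.i += 1
        return tok

    def _fail(self, message: str) -> None:
        tok = self._peek()
        pos = tok.pos if tok is not None else len(self.text)
        raise ExpressionSyntaxError(message, pos)

    def parse(self) -> ConditionExpr:
        expr = self._or_expr()
        if self._peek() is not None:
            self._fail(f"unexpected token {self._peek().text!r}")
        return expr

    def _or_expr(self) -> ConditionExpr:
        operands = [self._and_expr()]
        while (tok := self._peek()) is not None and tok.kind == "or":
            self._next()
            operands.append(self._and_expr())
        return operands[0] if len(operands) == 1 else BoolOp("or", tuple(operands))

    def _and_expr(self) -> ConditionExpr:
        operands = [self._not_expr()]
        while (tok := self._peek()) is not None and tok.kind == "and":
            self._next()
            operands.append(self._not_expr())
        return operands[0] if len(operands) == 1 else BoolOp("and", tuple(operands))

    def _not_expr(self) -> ConditionExpr:
        tok = self._peek()
        if tok is not None and tok.kind == "not":
            self._next()
            return Not(self._not_expr())
        return self._comparison()

    def _comparison(self) -> ConditionExpr:
        left = self._operand()
        tok = self._peek()
        if tok is not None and tok.kind == "op":
            self._next()
            right = self._operand()
            return Comparison(tok.text, left, right)
        return left

    def _operand(self) -> ConditionExpr:
        tok = self._peek()
        if tok is None:
            self._fail("unexpected end of expression")
        assert tok is not None
        if tok.kind == "lparen":
            self._next()
            inner = self._or_expr()
            closing = self._peek()
            if closing is None or closing.kind != "rparen":
                self._fail("expected ')'")
            self._next()
            return inner
        if tok.kind == "number":
            self._next()
            text = tok.text
            return Literal(float(text) if "." in text else int(text))
        if tok.kind == "string":
            self._next()
            return Literal(tok.text[1:-1])
        if tok.kind in ("true", "false"):
            self._next()
            return Literal(tok.kind == "true")
        if tok.kind == "ident":
            self._next()
            return VarRef(tok.text)
        self._fail(f"unexpected token {tok.text!r}")
        raise AssertionError("unreachable")


def parse_expression(text: str) -> ConditionExpr:
    """Parse a condition expression; raises ExpressionSyntaxError with the
    offending position on invalid input."""
    if not text or not text.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    return _Parser(text).parse()


def variables_of(expr: ConditionExpr) -> set[str]:
    """All variable names referenced anywhere in the expression."""
    if isinstance(expr, VarRef):
        return {expr.name}
    if isinstance(expr, Literal):
        return set()
    if isinstance(expr, Not):
        return variables_of(expr.operand)
    if isinstance(expr, Comparison):
        return variables_of(expr.left) | variables_of(expr.right)
    if isinstance(expr, BoolOp):
        out: set[str] = set()
        for op in expr.operands:
            out |= variables_of(op)
        return out
    raise TypeError(f"not a ConditionExpr: {expr!r}")


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

_ABSENT = object()


def _kind(value: Scalar) -> str:
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, (int, float)):
        return "number"
    return "string"


def _operand_value(expr: ConditionExpr, ctx: TreatmentContext):
    """Scalar value of a comparison operand, or _ABSENT for a missing variable."""
    if isinstance(expr, Literal):
        return expr.value
    if isinstance(expr, VarRef):
        present, value = ctx.lookup(expr.name)
        return value if present else _ABSENT
    # a nested logical expression used as a comparison operand: evaluate to
    # a truth value (UNKNOWN maps to absence)
    tri = evaluate(expr, ctx)
    if tri == TriState.UNKNOWN:
        return _ABSENT
    return tri == TriState.TRUE


def _compare(op: str, expr: Comparison, ctx: TreatmentContext) -> TriState:
    left = _operand_value(expr.left, ctx)
    right = _operand_value(expr.right, ctx)
    if left is _ABSENT or right is _ABSENT:
        return TriState.UNKNOWN

    def _name(side: ConditionExpr) -> str:
        return side.name if isinstance(side, VarRef) else repr(side)

    lk, rk = _kind(left), _kind(right)
    if lk != rk:
        raise EvaluationError(
            f"cannot compare {_name(expr.left)} ({lk}) with "
            f"{_name(expr.right)} ({rk})")
    if op in ("==", "!="):
        result = left == right
        return TriState.of(result if op == "==" else not result)
    if lk != "number":
        raise EvaluationError(
            f"ordering comparison {op!r} requires numbers, got {lk} "
            f"({_name(expr.left)})")
    table: dict[str, Callable[[float, float], bool]] = {
        "<": lambda a, b: a < b,
        "<=": lambda a, b: a <= b,
        ">": lambda a, b: a > b,
        ">=": lambda a, b: a >= b,
    }
    return TriState.of(table[op](left, right))


def _truth(expr: ConditionExpr, ctx: TreatmentContext) -> TriState:
    """Truth value of an expression in boolean position."""
    if isinstance(expr, Literal):
        if not isinstance(expr.value, bool):
            raise EvaluationError(
                f"literal {expr.value!r} used where a boolean is required")
        return TriState.of(expr.value)
    if isinstance(expr, VarRef):
        present, value = ctx.lookup(expr.name)
        if not present:
            return TriState.UNKNOWN
        if not isinstance(value, bool):
            raise EvaluationError(
                f"variable {expr.name!r} has {_kind(value)} value {value!r} "
                "where a boolean is required")
        return TriState.of(value)
    if isinstance(expr, Comparison):
        return _compare(expr.op, expr, ctx)
    if isinstance(expr, Not):
        return not3(_truth(expr.operand, ctx))
    if isinstance(expr, BoolOp):
        values = [_truth(op, ctx) for op in expr.operands]
        return and3(*values) if expr.op == "and" else or3(*values)
    raise TypeError(f"not a ConditionExpr: {expr!r}")


def evaluate(expr: ConditionExpr, ctx: TreatmentContext) -> TriState:
    """Evaluate a parsed condition under Kleene semantics.

    Absent variables yield UNKNOWN; type mismatches between *present* values
    raise :class:`EvaluationError` (they signal a model/context contract
    violation, not missing data).  Evaluation is pure.
    """
    return _truth(expr, ctx)


# --------------------------------------------------------------------------
# Medical-criteria resolver
# --------------------------------------------------------------------------

CriterionResolver = Callable[[str, TreatmentContext], TriState]
"""Pluggable hook for an external medical-knowledge layer: maps a criterion
id plus context to a truth value.  Must be pure."""


def default_resolver(criterion_id: str, ctx: TreatmentContext) -> TriState:
    """Treats the criterion id itself as a condition expression."""
    return evaluate(parse_expression(criterion_id), ctx)


def resolve_criterion(
    criterion_id: str,
    ctx: TreatmentContext,
    resolver: CriterionResolver = default_resolver,
    warnings: list[str] | None = None,
) -> TriState:
    """Resolve a medical criterion, degrading failures to UNKNOWN.

    A raising resolver must not crash contextualization (the pipeline is
    stateless and re-run in full on every context change), so any exception
    is converted to UNKNOWN and recorded in *warnings* when supplied.
    """
    try:
        return resolver(criterion_id, ctx)
    except Exception as exc:  # noqa: BLE001 - contract: degrade, never crash
        if warnings is not None:
            warnings.append(
                f"criterion {criterion_id!r} could not be resolved: {exc}")
        return TriState.UNKNOWN
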