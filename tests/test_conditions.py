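"""Condition grammar and Kleene three-valued evaluation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cigpath.conditions import (
    TreatmentContext,
    TriState,
    and3,
    evaluate,
    not3,
    or3,
    parse_expression,
    resolve_criterion,
    variables_of,
)
from cigpath.errors import EvaluationError, ExpressionSyntaxError

T, F, U = TriState.TRUE, TriState.FALSE, TriState.UNKNOWN

# Kleene's strong three-valued truth tables, written out independently of
# the implementation's min/max trick.
AND_TABLE = {
    (T, T): T, (T, F): F, (T, U): U,
    (F, T): F, (F, F): F, (F, U): F,
    (U, T): U, (U, F): F, (U, U): U,
}
OR_TABLE = {
    (T, T): T, (T, F): T, (T, U): T,
    (F, T): T, (F, F): F, (F, U): U,
    (U, T): T, (U, F): U, (U, U): U,
}
NOT_TABLE = {T: F, F: T, U: U}


def test_kleene_truth_tables_exhaustive():
    for a, b in itertools.product(TriState, repeat=2):
        assert and3(a, b) == AND_TABLE[(a, b)]
        assert or3(a, b) == OR_TABLE[(a, b)]
    for a in TriState:
        assert not3(a) == NOT_TABLE[a]


def test_kleene_identities():
    for x in TriState:
        assert and3(F, x) == F
        assert or3(T, x) == T
        assert and3(T, x) == x
        assert or3(F, x) == x
    # commutative / associative over all triples
    for a, b, c in itertools.product(TriState, repeat=3):
        assert and3(a, b) == and3(b, a)
        assert or3(a, b) == or3(b, a)
        assert and3(and3(a, b), c) == and3(a, and3(b, c))
        assert or3(or3(a, b), c) == or3(a, or3(b, c))


def test_connectives_monotone_in_information_order():
    """Required for fixpoint convergence: raising an argument in
    FALSE <= UNKNOWN <= TRUE never lowers the result."""
    order = [F, U, T]
    for f in (and3, or3):
        for a, b in itertools.product(order, repeat=2):
            for b2 in order:
                if order.index(b2) >= order.index(b):
                    assert order.index(f(a, b2)) >= order.index(f(a, b))


@pytest.mark.parametrize("text, variables", [
    ("A == true", {"A"}),
    ("not (x < 3 and y == 'high')", {"x", "y"}),
    ("a or b and not c", {"a", "b", "c"}),
    ("temperature >= 38.5", {"temperature"}),
])
def test_parse_well_formed(text, variables):
    expr = parse_expression(text)
    assert variables_of(expr) == variables


@pytest.mark.parametrize("text, position", [
    ("A == ", 5),
    ("", 0),
    ("   ", 0),
    ("(A == true", 10),
    ("A ==  == B", 6),
])
def test_parse_errors_carry_position(text, position):
    with pytest.raises(ExpressionSyntaxError) as exc:
        parse_expression(text)
    assert exc.value.position == position


def test_overlong_identifier_rejected():
    with pytest.raises(ExpressionSyntaxError):
        parse_expression("x" * 257 + " == true")


@pytest.mark.parametrize("ctx, expected", [
    (TreatmentContext(variables={"A": True}), T),
    (TreatmentContext(variables={"A": False}), F),
    (TreatmentContext(), U),
])
def test_simple_equality_three_valued(ctx, expected):
    assert evaluate(parse_expression("A == true"), ctx) == expected


def test_unknown_dominated_by_or_truth():
    assert evaluate(parse_expression("A == true or true"),
                    TreatmentContext()) == T


def test_no_cross_condition_reasoning():
    """'A == true and A == false' is unsatisfiable, but Kleene evaluation is
    deliberately local: with A absent both conjuncts are UNKNOWN."""
    expr = parse_expression("A == true and A == false")
    assert evaluate(expr, TreatmentContext()) == U


@pytest.mark.parametrize("text, ctx, expected", [
    ("x < 3", {"x": 2}, T),
    ("x < 3", {"x": 3}, F),
    ("x <= 3 and x >= 3", {"x": 3}, T),
    ("y == 'high'", {"y": "high"}, T),
    ("y != 'high'", {"y": "low"}, T),
    ("not (x < 3 and y == 'high')", {"x": 1, "y": "high"}, F),
    # x absent: x < 3 is UNKNOWN, but the failed conjunct decides: not(F) = T
    ("not (x < 3 and y == 'high')", {"y": "low"}, T),
    ("not (x < 3 and y == 'high')", {"y": "high"}, U),
])
def test_evaluate_examples(text, ctx, expected):
    assert evaluate(parse_expression(text),
                    TreatmentContext(variables=ctx)) == expected


@pytest.mark.parametrize("text, ctx", [
    ("x < 3", {"x": "abc"}),            # ordering on a string
    ("y < 'high'", {"y": "low"}),       # ordering between strings
    ("x == 'abc'", {"x": 3}),           # equality across kinds
    ("x and true", {"x": 7}),           # number in boolean position
    ("3 or true", {}),                  # literal number in boolean position
])
def test_type_mismatch_on_present_values_raises(text, ctx):
    with pytest.raises(EvaluationError):
        evaluate(parse_expression(text), TreatmentContext(variables=ctx))


def test_absent_variable_beats_type_checking():
    # absence means "no data yet", which is UNKNOWN, not an error
    assert evaluate(parse_expression("x < 3"), TreatmentContext()) == U


def test_executed_outcome_exposed_and_shadowed():
    ctx = TreatmentContext(executed={"A": True}, variables={"A": False})
    assert ctx.is_executed("A")
    assert evaluate(parse_expression("A == true"), ctx) == F  # explicit wins


def test_evaluate_is_pure():
    expr = parse_expression("a and not b or c == 2")
    ctx = TreatmentContext(variables={"a": True, "c": 2})
    assert evaluate(expr, ctx) == evaluate(expr, ctx) == T


# -- randomized agreement with ordinary boolean logic -----------------------

_bool_expr = st.recursive(
    st.sampled_from(["a", "b", "c", "true", "false"]),
    lambda sub: st.one_of(
        st.tuples(st.just("not"), sub).map(lambda t: f"not ({t[1]})"),
        st.tuples(sub, st.sampled_from(["and", "or"]), sub).map(
            lambda t: f"({t[0]}) {t[1]} ({t[2]})"),
        st.tuples(st.sampled_from(["a", "b", "c"]),
                  st.sampled_from(["==", "!="]),
                  st.sampled_from(["true", "false"])).map(
            lambda t: f"{t[0]} {t[1]} {t[2]}"),
    ),
    max_leaves=12,
)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(text=_bool_expr, a=st.booleans(), b=st.booleans(), c=st.booleans())
def test_two_valued_contexts_reduce_to_boolean_logic(text, a, b, c):
    """With every variable present, Kleene evaluation equals ordinary
    two-valued evaluation (independent oracle: Python's own operators)."""
    ctx = TreatmentContext(variables={"a": a, "b": b, "c": c})
    got = evaluate(parse_expression(text), ctx)
    expected = eval(  # noqa: S307 - trusted generated input, independent oracle
        text.replace("true", "True").replace("false", "False"),
        {"a": a, "b": b, "c": c},
    )
    assert got == TriState.of(expected)
    assert got in (T, F)


# -- criterion resolver -----------------------------------------------------

def test_default_resolver_delegates_to_expression_evaluation():
    ctx = TreatmentContext(variables={"B": True})
    assert resolve_criterion("B == true", ctx) == T


def test_custom_resolver_used():
    assert resolve_criterion("anything", TreatmentContext(),
                             resolver=lambda cid, ctx: U) == U


def test_raising_resolver_degrades_to_unknown_with_warning():
    warnings: list[str] = []

    def broken(cid, ctx):
        raise RuntimeError("knowledge base offline")

    assert resolve_criterion("crit-1", TreatmentContext(),
                             resolver=broken, warnings=warnings) == U
    assert warnings and "crit-1" in warnings[0]
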