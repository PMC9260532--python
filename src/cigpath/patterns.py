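"""Workflow-control-pattern fixtures, random structured models and a
brute-force oracle.

The six canonical patterns (sequence, parallel split, synchronization,
exclusive choice, simple merge, structured loop) form the test surface for
the inference engine.  The synchronization fixture carries the nine
exhaustive two-task contexts with their expected temporal roles; the other
patterns carry exhaustive {executed-true, executed-false, absent} context
grids whose expectations are computed by the independent oracle.

The oracle decides reachability by enumerating every two-valued completion
of the absent variables referenced by edge conditions: a vertex is pruned
iff it is unreachable under *all* completions, and a task can recur iff it
lies on a reachable cycle under *some* completion.  Arrival (what is enabled
now) uses only conditions that are decidedly true.  The oracle shares no
traversal code with the engine; it exists to check the engine, not to
replace it.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .bpmn import BPMN_NS, write_context
from .conditions import (
    Scalar,
    TreatmentContext,
    TriState,
    evaluate,
    parse_expression,
    variables_of,
)
from .contextualize import RoleAssignment, TemporalRole
from .errors import OracleScaleError, UsageError
from .model import GuidelineModel, VertexType

__all__ = [
    "PatternCase",
    "PatternFixture",
    "PATTERN_NAMES",
    "generate_pattern",
    "generate_random_model",
    "generate_random_context",
    "oracle_roles",
    "export_fixture",
    "model_to_bpmn",
]

GRID_CAP_TASKS = 6  # exhaustive grids are 3^n contexts; capped at 3^6


@dataclass(frozen=True)
class PatternCase:
    name: str
    context: TreatmentContext
    # task id -> expected role, or None if the task is expected to be pruned;
    # the whole field is None for unspecified expectations
    expected: dict[str, TemporalRole | None] | None


@dataclass(frozen=True)
class PatternFixture:
    name: str
    model: GuidelineModel
    cases: tuple[PatternCase, ...]


# --------------------------------------------------------------------------
# Canonical pattern models
# --------------------------------------------------------------------------

def _sequence_model() -> GuidelineModel:
    m = GuidelineModel(id="sequence")
    m.add_vertex("start", VertexType.START, "Start")
    for t in ("T1", "T2", "T3"):
        m.add_vertex(t, VertexType.TASK, f"Task {t}")
    m.add_vertex("end", VertexType.END, "End")
    chain = ["start", "T1", "T2", "T3", "end"]
    for i, (u, v) in enumerate(zip(chain, chain[1:]), 1):
        m.add_edge(f"f{i}", u, v)
    return m


def _parallel_split_model() -> GuidelineModel:
    m = GuidelineModel(id="parallel_split")
    m.add_vertex("start", VertexType.START, "Start")
    m.add_vertex("split", VertexType.AND_GATEWAY, "Split")
    m.add_vertex("A", VertexType.TASK, "Task A")
    m.add_vertex("B", VertexType.TASK, "Task B")
    m.add_vertex("endA", VertexType.END, "End A")
    m.add_vertex("endB", VertexType.END, "End B")
    m.add_edge("f1", "start", "split")
    m.add_edge("f2", "split", "A")
    m.add_edge("f3", "split", "B")
    m.add_edge("f4", "A", "endA")
    m.add_edge("f5", "B", "endB")
    return m


def _synchronization_model() -> GuidelineModel:
    """Parallel branches A and B converge on a synchronizing join whose
    incoming flows are guarded on the recorded task outcomes."""
    m = GuidelineModel(id="synchronization")
    m.add_vertex("start", VertexType.START, "Start")
    m.add_vertex("split", VertexType.AND_GATEWAY, "Split")
    m.add_vertex("A", VertexType.TASK, "Task A")
    m.add_vertex("B", VertexType.TASK, "Task B")
    m.add_vertex("join", VertexType.AND_GATEWAY, "Join")
    m.add_vertex("C", VertexType.TASK, "Task C")
    m.add_vertex("end", VertexType.END, "End")
    m.add_edge("f1", "start", "split")
    m.add_edge("f2", "split", "A")
    m.add_edge("f3", "split", "B")
    m.add_edge("f4", "A", "join", condition="A == true")
    m.add_edge("f5", "B", "join", condition="B == true")
    m.add_edge("f6", "join", "C")
    m.add_edge("f7", "C", "end")
    return m


def _exclusive_choice_model() -> GuidelineModel:
    m = GuidelineModel(id="exclusive_choice")
    m.add_vertex("start", VertexType.START, "Start")
    m.add_vertex("D", VertexType.TASK, "Decision task")
    m.add_vertex("split", VertexType.XOR_GATEWAY, "Choice")
    m.add_vertex("T1", VertexType.TASK, "Task T1")
    m.add_vertex("T2", VertexType.TASK, "Task T2")
    m.add_vertex("endA", VertexType.END, "End A")
    m.add_vertex("endB", VertexType.END, "End B")
    m.add_edge("f1", "start", "D")
    m.add_edge("f2", "D", "split")
    m.add_edge("f3", "split", "T1", condition="D == true")
    m.add_edge("f4", "split", "T2", condition="D == false")
    m.add_edge("f5", "T1", "endA")
    m.add_edge("f6", "T2", "endB")
    return m


def _simple_merge_model() -> GuidelineModel:
    m = GuidelineModel(id="simple_merge")
    m.add_vertex("start", VertexType.START, "Start")
    m.add_vertex("D", VertexType.TASK, "Decision task")
    m.add_vertex("split", VertexType.XOR_GATEWAY, "Choice")
    m.add_vertex("A", VertexType.TASK, "Task A")
    m.add_vertex("B", VertexType.TASK, "Task B")
    m.add_vertex("join", VertexType.XOR_GATEWAY, "Merge")
    m.add_vertex("C", VertexType.TASK, "Task C")
    m.add_vertex("end", VertexType.END, "End")
    m.add_edge("f1", "start", "D")
    m.add_edge("f2", "D", "split")
    m.add_edge("f3", "split", "A", condition="D == true")
    m.add_edge("f4", "split", "B")  # default branch
    m.add_edge("f5", "A", "join")
    m.add_edge("f6", "B", "join")
    m.add_edge("f7", "join", "C")
    m.add_edge("f8", "C", "end")
    return m


def _structured_loop_model() -> GuidelineModel:
    """Repeat T1 while its recorded outcome is false; then proceed to T2."""
    m = GuidelineModel(id="structured_loop")
    m.add_vertex("start", VertexType.START, "Start")
    m.add_vertex("j", VertexType.XOR_GATEWAY, "Loop entry")
    m.add_vertex("T1", VertexType.TASK, "Task T1")
    m.add_vertex("s", VertexType.XOR_GATEWAY, "Repeat?")
    m.add_vertex("T2", VertexType.TASK, "Task T2")
    m.add_vertex("end", VertexType.END, "End")
    m.add_edge("f1", "start", "j")
    m.add_edge("f2", "j", "T1")
    m.add_edge("f3", "T1", "s")
    m.add_edge("f4", "s", "j", condition="T1 == false")
    m.add_edge("f5", "s", "T2")  # default: leave the loop
    m.add_edge("f6", "T2", "end")
    return m


_MODEL_BUILDERS = {
    "sequence": _sequence_model,
    "parallel_split": _parallel_split_model,
    "synchronization": _synchronization_model,
    "exclusive_choice": _exclusive_choice_model,
    "simple_merge": _simple_merge_model,
    "structured_loop": _structured_loop_model,
}

PATTERN_NAMES = tuple(_MODEL_BUILDERS)

# Exhaustive synchronization contexts and their expected inference:
# (case, outcome of A, outcome of B, role of A, role of B, role of C),
# with None meaning "not executed" on the input side and "pruned" on the
# expectation side.
_P, _R, _F = TemporalRole.PAST, TemporalRole.PRESENT, TemporalRole.FUTURE
SYNCHRONIZATION_CASES: tuple[tuple[str, bool | None, bool | None,
                                   TemporalRole, TemporalRole,
                                   TemporalRole | None], ...] = (
    ("Pat01", True, True, _P, _P, _R),
    ("Pat02", True, None, _P, _R, _F),
    ("Pat03", True, False, _P, _P, None),
    ("Pat04", None, True, _R, _P, _F),
    ("Pat05", None, None, _R, _R, _F),
    ("Pat06", None, False, _R, _P, None),
    ("Pat07", False, True, _P, _P, None),
    ("Pat08", False, None, _P, _R, None),
    ("Pat09", False, False, _P, _P, None),
)


def _grid_cases(model: GuidelineModel) -> tuple[PatternCase, ...]:
    """Exhaustive contexts assigning each task executed-true, executed-false
    or absent, with oracle-computed expectations."""
    task_ids = [v.id for v in model.tasks()]
    if len(task_ids) > GRID_CAP_TASKS:
        task_ids = task_ids[:GRID_CAP_TASKS]
    codes = {True: "t", False: "f", None: "a"}
    cases = []
    for values in itertools.product((True, False, None), repeat=len(task_ids)):
        executed = {tid: val for tid, val in zip(task_ids, values)
                    if val is not None}
        ctx = TreatmentContext(executed=executed)
        name = "ctx_" + "".join(codes[v] for v in values)
        oracle = oracle_roles(model, ctx)
        expected: dict[str, TemporalRole | None] = {}
        for v in model.tasks():
            expected[v.id] = oracle.roles.get(v.id)  # None when pruned
        cases.append(PatternCase(name=name, context=ctx, expected=expected))
    return tuple(cases)


def generate_pattern(name: str) -> PatternFixture:
    """Canonical model plus test contexts for one workflow control pattern."""
    try:
        model = _MODEL_BUILDERS[name]()
    except KeyError:
        raise UsageError(
            f"unknown pattern {name!r}; supported: {', '.join(PATTERN_NAMES)}"
        ) from None
    if name == "synchronization":
        cases = []
        for case, val_a, val_b, role_a, role_b, role_c in SYNCHRONIZATION_CASES:
            executed: dict[str, Scalar] = {}
            if val_a is not None:
                executed["A"] = val_a
            if val_b is not None:
                executed["B"] = val_b
            cases.append(PatternCase(
                name=case,
                context=TreatmentContext(executed=executed),
                expected={"A": role_a, "B": role_b, "C": role_c},
            ))
        return PatternFixture(name=name, model=model, cases=tuple(cases))
    return PatternFixture(name=name, model=model, cases=_grid_cases(model))


# --------------------------------------------------------------------------
# Random structured models
# --------------------------------------------------------------------------

def generate_random_model(
    seed: int,
    n_tasks: int,
    p_xor: float = 0.25,
    p_and: float = 0.2,
    p_loop: float = 0.15,
) -> GuidelineModel:
    """Block-structured random model: recursive composition of sequence,
    exclusive-choice, parallel and loop blocks.

    Always structurally valid; every condition references a fresh variable
    (V1, V2, ...) so conditions are pairwise independent.  The same seed and
    parameters yield the identical model.
    """
    if n_tasks < 1:
        raise UsageError("n_tasks must be >= 1")
    for p in (p_xor, p_and, p_loop):
        if not 0.0 <= p <= 1.0:
            raise UsageError("probabilities must lie in [0, 1]")
    rng = random.Random(seed)
    m = GuidelineModel(id=f"random_{seed}")
    counters = {"t": 0, "g": 0, "v": 0, "f": 0}

    def fresh(kind: str) -> str:
        counters[kind] += 1
        return {"t": "T", "g": "G", "v": "V", "f": "f"}[kind] + str(counters[kind])

    def edge(u: str, v: str, condition: str | None = None) -> None:
        m.add_edge(fresh("f"), u, v, condition=condition)

    def task() -> tuple[str, str]:
        tid = fresh("t")
        m.add_vertex(tid, VertexType.TASK, f"Task {tid}")
        return tid, tid

    def build(budget: int, loop_ok: bool = True) -> tuple[str, str]:
        r = rng.random()
        if budget >= 2 and r < p_xor:
            return xor_block(budget)
        if budget >= 2 and r < p_xor + p_and:
            return and_block(budget)
        if loop_ok and r < p_xor + p_and + p_loop:
            return loop_block(budget)
        if budget >= 2:
            return seq_block(budget)
        return task()

    def seq_block(budget: int) -> tuple[str, str]:
        left = rng.randint(1, budget - 1)
        en1, ex1 = build(left)
        en2, ex2 = build(budget - left)
        edge(ex1, en2)
        return en1, ex2

    def _branches(budget: int, gateway: VertexType, conditioned: bool
                  ) -> tuple[str, str]:
        split = fresh("g")
        m.add_vertex(split, gateway, split)
        left = rng.randint(1, budget - 1)
        branches = [build(left), build(budget - left)]
        join = fresh("g")
        m.add_vertex(join, gateway, join)
        use_default = conditioned and rng.random() < 0.5
        for i, (en, ex) in enumerate(branches):
            cond = None
            if conditioned and not (use_default and i == len(branches) - 1):
                cond = f"{fresh('v')} == true"
            edge(split, en, condition=cond)
            edge(ex, join)
        return split, join

    def xor_block(budget: int) -> tuple[str, str]:
        return _branches(budget, VertexType.XOR_GATEWAY, conditioned=True)

    def and_block(budget: int) -> tuple[str, str]:
        return _branches(budget, VertexType.AND_GATEWAY, conditioned=False)

    def loop_block(budget: int) -> tuple[str, str]:
        j = fresh("g")
        m.add_vertex(j, VertexType.XOR_GATEWAY, j)
        # the immediate body is never itself a loop: keeps the number of
        # loop conditions proportional to the task budget
        en, ex = build(budget, loop_ok=False)
        s = fresh("g")
        m.add_vertex(s, VertexType.XOR_GATEWAY, s)
        edge(j, en)
        edge(ex, s)
        edge(s, j, condition=f"{fresh('v')} == true")  # repeat
        return j, s  # the fall-through edge is added by the caller wiring

    m.add_vertex("start", VertexType.START, "Start")
    entry, exit_ = build(n_tasks)
    m.add_vertex("end", VertexType.END, "End")
    edge("start", entry)
    edge(exit_, "end")
    return m


def condition_variables(model: GuidelineModel) -> list[str]:
    """Variables referenced by edge conditions, in edge document order."""
    seen: list[str] = []
    for e in sorted(model.edges.values(), key=lambda e: e.order):
        if e.condition is None:
            continue
        for name in sorted(variables_of(parse_expression(e.condition))):
            if name not in seen:
                seen.append(name)
    return seen


def generate_random_context(
    model: GuidelineModel, seed: int, max_unknown: int = 12
) -> TreatmentContext:
    """Random context: each task executed-true / executed-false / unexecuted,
    each condition variable true / false / absent.

    At most *max_unknown* condition variables are left absent (surplus ones
    receive a random boolean), keeping completion-enumeration oracles
    tractable on the same contexts.
    """
    rng = random.Random(seed)
    executed: dict[str, Scalar] = {}
    for v in model.tasks():
        r = rng.random()
        if r < 1 / 3:
            executed[v.id] = True
        elif r < 2 / 3:
            executed[v.id] = False
    variables: dict[str, Scalar] = {}
    unknown = 0
    for name in condition_variables(model):
        r = rng.random()
        if r < 0.35:
            variables[name] = True
        elif r < 0.7:
            variables[name] = False
        elif unknown < max_unknown:
            unknown += 1
        else:
            variables[name] = rng.random() < 0.5
    return TreatmentContext(executed=executed, variables=variables)


# --------------------------------------------------------------------------
# Brute-force oracle
# --------------------------------------------------------------------------

def _xor_splits(model: GuidelineModel) -> list[list]:
    return [model.out_edges(v.id) for v in model.vertices.values()
            if v.type == VertexType.XOR_GATEWAY and model.out_degree(v.id) > 1]


def _resolve_two_valued(model: GuidelineModel, raw: dict[str, bool]
                        ) -> dict[str, bool]:
    """Exclusive-split winner selection when every condition is two-valued."""
    resolved = dict(raw)
    for out in _xor_splits(model):
        conditioned = [e for e in out if e.condition is not None]
        defaults = [e for e in out if e.condition is None]
        winners = [e for e in conditioned if raw[e.id]]
        for e in out:
            resolved[e.id] = False
        if winners:
            resolved[min(winners, key=lambda e: e.order).id] = True
        elif defaults:
            resolved[min(defaults, key=lambda e: e.order).id] = True
    return resolved


def _reachable(model: GuidelineModel, edge_true: dict[str, bool]) -> set[str]:
    """Two-valued reachability fixpoint (parallel joins need all inputs)."""
    start = model.start.id
    reach = {start}
    changed = True
    while changed:
        changed = False
        for vid, v in model.vertices.items():
            if vid in reach:
                continue
            incoming = model.in_edges(vid)
            if not incoming:
                continue
            ok = [e.source in reach and edge_true[e.id] for e in incoming]
            join = (v.type == VertexType.AND_GATEWAY and len(incoming) > 1)
            if (all(ok) if join else any(ok)):
                reach.add(vid)
                changed = True
    return reach


def _cycle_vertices(vertices: set[str], edges: list[tuple[str, str]]) -> set[str]:
    """Vertices on a directed cycle (Kosaraju, hand-rolled: the oracle shares
    no graph code with the engine)."""
    fwd: dict[str, list[str]] = {v: [] for v in vertices}
    back: dict[str, list[str]] = {v: [] for v in vertices}
    self_loops = set()
    for u, v in edges:
        if u in vertices and v in vertices:
            fwd[u].append(v)
            back[v].append(u)
            if u == v:
                self_loops.add(u)

    order: list[str] = []
    seen: set[str] = set()
    for root in vertices:
        if root in seen:
            continue
        stack = [(root, iter(fwd[root]))]
        seen.add(root)
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, iter(fwd[nxt])))
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                stack.pop()

    assigned: set[str] = set()
    result = set(self_loops)
    for root in reversed(order):
        if root in assigned:
            continue
        component = [root]
        assigned.add(root)
        stack2 = [root]
        while stack2:
            node = stack2.pop()
            for prev in back[node]:
                if prev not in assigned:
                    assigned.add(prev)
                    component.append(prev)
                    stack2.append(prev)
        if len(component) > 1:
            result |= set(component)
    return result


def _definitely_true_edges(model: GuidelineModel, ctx: TreatmentContext
                           ) -> dict[str, bool]:
    """Edges whose guard is decidedly satisfied under the raw context, with
    exclusive-split winner selection applied."""
    tri = {}
    for e in model.edges.values():
        if e.condition is None:
            tri[e.id] = TriState.TRUE
        else:
            tri[e.id] = evaluate(parse_expression(e.condition), ctx)
    definite = {eid: (val == TriState.TRUE) for eid, val in tri.items()}
    for out in _xor_splits(model):
        conditioned = [e for e in out if e.condition is not None]
        defaults = [e for e in out if e.condition is None]
        for e in out:
            definite[e.id] = False
        # definitely chosen: condition satisfied and every earlier-priority
        # condition definitely failed (a pending earlier sibling could still
        # claim the token); default fires when all conditions failed
        all_false_so_far = True
        for e in conditioned:
            if tri[e.id] == TriState.TRUE and all_false_so_far:
                definite[e.id] = True
            all_false_so_far = all_false_so_far and tri[e.id] == TriState.FALSE
        if defaults and all_false_so_far:
            definite[min(defaults, key=lambda e: e.order).id] = True
    return definite


def _oracle_arrival(model: GuidelineModel, ctx: TreatmentContext
                    ) -> dict[str, bool]:
    true_edges = _definitely_true_edges(model, ctx)
    start = model.start.id
    arrived = {vid: False for vid in model.vertices}
    arrived[start] = True
    changed = True
    while changed:
        changed = False
        for vid, v in model.vertices.items():
            if arrived[vid]:
                continue
            incoming = model.in_edges(vid)
            if not incoming:
                continue

            def delivers(e) -> bool:
                if not true_edges[e.id]:
                    return False
                src = model.vertices[e.source]
                if src.type == VertexType.TASK:
                    return ctx.is_executed(src.id)
                return arrived[src.id]

            join = (v.type == VertexType.AND_GATEWAY and len(incoming) > 1)
            if (all(delivers(e) for e in incoming) if join
                    else any(delivers(e) for e in incoming)):
                arrived[vid] = True
                changed = True
    return arrived


def oracle_roles(model: GuidelineModel, ctx: TreatmentContext,
                 cap: int = 16) -> RoleAssignment:
    """Brute-force reference inference by completion enumeration.

    Enumerates every boolean completion of the absent variables referenced
    by edge conditions (refusing when more than *cap* are absent).  A vertex
    is pruned iff unreachable under all completions; a task can recur iff it
    lies on a cycle of satisfied edges, reachable in the same completion.
    PAST/PRESENT/FUTURE follow the same rules the engine defines, but every
    ingredient is recomputed here with independent traversal code.
    """
    referenced: list[str] = condition_variables(model)
    absent = [name for name in referenced if not ctx.lookup(name)[0]]
    if len(absent) > cap:
        raise OracleScaleError(
            f"{len(absent)} unknown variables exceed the oracle cap of {cap}")

    parsed = {e.id: (parse_expression(e.condition)
                     if e.condition is not None else None)
              for e in model.edges.values()}

    ever_reachable: set[str] = set()
    recurring: set[str] = set()
    for bits in itertools.product((True, False), repeat=len(absent)):
        completion = TreatmentContext(
            executed=dict(ctx.executed),
            variables={**ctx.variables, **dict(zip(absent, bits))},
        )
        raw = {}
        for e in model.edges.values():
            expr = parsed[e.id]
            if expr is None:
                raw[e.id] = True
            else:
                value = evaluate(expr, completion)
                if value == TriState.UNKNOWN:
                    raise OracleScaleError(
                        f"condition on edge {e.id!r} remains undecided under "
                        "a full completion; the oracle only supports "
                        "boolean-complete conditions")
                raw[e.id] = value == TriState.TRUE
        edge_true = _resolve_two_valued(model, raw)
        reach = _reachable(model, edge_true)
        ever_reachable |= reach
        live_edges = [(e.source, e.target) for e in model.edges.values()
                      if edge_true[e.id]]
        recurring |= _cycle_vertices(reach, live_edges)

    arrived = _oracle_arrival(model, ctx)

    roles: dict[str, TemporalRole] = {}
    pruned: set[str] = set()
    for v in model.vertices.values():
        if v.id not in ever_reachable:
            pruned.add(v.id)
        elif v.type == VertexType.TASK:
            if ctx.is_executed(v.id) and v.id not in recurring:
                roles[v.id] = TemporalRole.PAST
            elif arrived[v.id]:
                roles[v.id] = TemporalRole.PRESENT
            else:
                roles[v.id] = TemporalRole.FUTURE
        else:
            roles[v.id] = (TemporalRole.PRESENT if arrived[v.id]
                           else TemporalRole.FUTURE)

    pruned_tasks = [v.id for v in model.vertices.values()
                    if v.id in pruned and v.type == VertexType.TASK]
    return RoleAssignment(roles=roles, pruned=pruned, reach={},
                          arrived=arrived, conditions={},
                          pruned_tasks=pruned_tasks)


# --------------------------------------------------------------------------
# Fixture export
# --------------------------------------------------------------------------

_XSI = "http://www.w3.org/2001/XMLSchema-instance"

_TYPE_TAGS = {
    VertexType.START: "startEvent",
    VertexType.END: "endEvent",
    VertexType.TASK: "task",
    VertexType.XOR_GATEWAY: "exclusiveGateway",
    VertexType.AND_GATEWAY: "parallelGateway",
}


def model_to_bpmn(model: GuidelineModel) -> str:
    """Emit the model as BPMN 2.0 XML (the subset the reader accepts)."""
    nsmap = {"bpmn": BPMN_NS, "xsi": _XSI}
    defs = etree.Element(f"{{{BPMN_NS}}}definitions", nsmap=nsmap,
                         targetNamespace="http://cigpath/fixtures")
    process = etree.SubElement(defs, f"{{{BPMN_NS}}}process",
                               id=model.id, isExecutable="false")
    for v in sorted(model.vertices.values(), key=lambda v: v.order):
        el = etree.SubElement(process, f"{{{BPMN_NS}}}{_TYPE_TAGS[v.type]}",
                              id=v.id)
        if v.label and v.label != v.id:
            el.set("name", v.label)
    for e in sorted(model.edges.values(), key=lambda e: e.order):
        el = etree.SubElement(process, f"{{{BPMN_NS}}}sequenceFlow",
                              id=e.id, sourceRef=e.source, targetRef=e.target)
        if e.condition is not None:
            cond = etree.SubElement(el, f"{{{BPMN_NS}}}conditionExpression")
            cond.set(f"{{{_XSI}}}type", "bpmn:tFormalExpression")
            cond.text = e.condition
    return etree.tostring(defs, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def export_fixture(fixture: PatternFixture, out_dir: str | Path) -> list[Path]:
    """Write the fixture model (BPMN XML) and one context JSON per case."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    bpmn_path = out / f"{fixture.name}.bpmn"
    bpmn_path.write_text(model_to_bpmn(fixture.model))
    written.append(bpmn_path)
    for case in fixture.cases:
        path = out / f"{case.name}.json"
        path.write_text(write_context(case.context))
        written.append(path)
    return written
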