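"""Temporal-role inference with implicit pruning.

Given a guideline model and a treatment context, every vertex receives
either a temporal role — PAST (executed and cannot occur again), PRESENT
(currently choosable) or FUTURE (possibly executed later, including
re-executable past tasks) — or is pruned because it is provably unreachable
under the context.  The computation is stateless and deterministic: the
whole inference is redone from scratch for every (model, context) pair.

Two fixpoints drive the inference:

* ``compute_reach`` — a three-valued reachability fixpoint.  An edge is
  available to the degree its source is reachable AND its condition holds
  (Kleene conjunction); a parallel join requires all incoming edges, any
  other vertex requires some incoming edge.  Values only ever increase in
  the order FALSE < UNKNOWN < TRUE, so the iteration terminates.  A vertex
  with reach FALSE is unreachable under every completion of the unknown
  data and is pruned.

* ``compute_arrival`` — a two-valued "confirmed facts" token game deciding
  what is enabled *now*: an edge delivers control only when its condition is
  definitely TRUE and its source has delivered (a task delivers when it was
  actually executed; events and gateways deliver when control arrived at
  them).

Exclusive (XOR) splits are resolved before either fixpoint: if some
outgoing condition is decidedly TRUE the lowest-document-order TRUE edge is
taken and its siblings are forced FALSE; if none is TRUE but some are
UNKNOWN, every non-FALSE edge (including an unconditioned default) remains
UNKNOWN; if all conditioned edges are FALSE the default edge (if any) is
taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .conditions import (
    TreatmentContext,
    TriState,
    and3,
    evaluate,
    not3,
    or3,
    parse_expression,
)
from .errors import EvaluationError
from .model import Diagnostic, Edge, GuidelineModel, Severity, VertexType

__all__ = [
    "TemporalRole",
    "RoleAssignment",
    "edge_conditions",
    "compute_reach",
    "compute_arrival",
    "can_recur",
    "assign_roles",
    "prune",
]


class TemporalRole(Enum):
    PAST = "past"
    PRESENT = "present"
    FUTURE = "future"


@dataclass
class RoleAssignment:
    """Result of temporal inference.

    ``roles`` and ``pruned`` partition the model's vertices.  ``reach``,
    ``arrived`` and ``conditions`` (effective per-edge condition values after
    XOR-split resolution) are exposed for debugging and downstream pruning.
    """

    roles: dict[str, TemporalRole]
    pruned: set[str]
    reach: dict[str, TriState]
    arrived: dict[str, bool]
    conditions: dict[str, TriState]
    diagnostics: list[Diagnostic] = field(default_factory=list)
    # pruned TASK vertices in document order (the user-facing pruned list)
    pruned_tasks: list[str] = field(default_factory=list)


def _evaluate_edge(edge: Edge, ctx: TreatmentContext) -> TriState:
    if edge.condition is None:
        return TriState.TRUE
    try:
        return evaluate(parse_expression(edge.condition), ctx)
    except EvaluationError as exc:
        raise EvaluationError(f"edge {edge.id!r}: {exc}") from exc


def edge_conditions(model: GuidelineModel, ctx: TreatmentContext
                    ) -> dict[str, TriState]:
    """Effective condition value per edge, after XOR-split resolution."""
    raw = {e.id: _evaluate_edge(e, ctx) for e in model.edges.values()}
    resolved = dict(raw)
    for v in model.vertices.values():
        if v.type != VertexType.XOR_GATEWAY:
            continue
        out = model.out_edges(v.id)
        if len(out) <= 1:
            continue
        # exclusive choice = "the first (document order) satisfied condition
        # wins; the default fires when every condition fails", translated
        # into Kleene logic: chosen(e_i) = cond(e_i) AND none of the earlier
        # conditions hold.  An edge with a TRUE condition therefore stays
        # UNKNOWN while an earlier-priority sibling is still undecided —
        # the pending data could hand the choice to the sibling.
        conditioned = [e for e in out if e.condition is not None]
        defaults = [e for e in out if e.condition is None]
        none_before = TriState.TRUE
        for e in conditioned:
            resolved[e.id] = and3(raw[e.id], none_before)
            none_before = and3(none_before, not3(raw[e.id]))
        for i, e in enumerate(defaults):
            # only the first default can ever fire
            resolved[e.id] = none_before if i == 0 else TriState.FALSE
    return resolved


def _is_and_join(model: GuidelineModel, vertex_id: str) -> bool:
    v = model.vertices[vertex_id]
    return v.type == VertexType.AND_GATEWAY and model.in_degree(vertex_id) > 1


def compute_reach(
    model: GuidelineModel,
    ctx: TreatmentContext,
    conditions: dict[str, TriState] | None = None,
) -> dict[str, TriState]:
    """Least fixpoint of three-valued reachability from the start vertex."""
    if conditions is None:
        conditions = edge_conditions(model, ctx)
    start_id = model.start.id
    reach = {vid: TriState.FALSE for vid in model.vertices}
    reach[start_id] = TriState.TRUE

    in_edges = {vid: model.in_edges(vid) for vid in model.vertices}
    changed = True
    while changed:
        changed = False
        for vid in model.vertices:
            if vid == start_id:
                continue
            incoming = in_edges[vid]
            if not incoming:
                continue
            avail = [and3(reach[e.source], conditions[e.id]) for e in incoming]
            new = and3(*avail) if _is_and_join(model, vid) else or3(*avail)
            if new != reach[vid]:
                # monotone: values only move up FALSE -> UNKNOWN -> TRUE
                reach[vid] = new
                changed = True
    return reach


def compute_arrival(
    model: GuidelineModel,
    ctx: TreatmentContext,
    conditions: dict[str, TriState] | None = None,
) -> dict[str, bool]:
    """Confirmed-facts token game: where has control definitely arrived?

    A task delivers control onward iff it was actually executed (its own
    arrival is irrelevant — recorded history is trusted); events and
    gateways deliver once control arrived at them.  An edge delivers only
    when its effective condition is decidedly TRUE.
    """
    if conditions is None:
        conditions = edge_conditions(model, ctx)
    start_id = model.start.id
    arrived = {vid: False for vid in model.vertices}
    arrived[start_id] = True

    def delivers(edge: Edge) -> bool:
        if conditions[edge.id] != TriState.TRUE:
            return False
        src = model.vertices[edge.source]
        if src.type == VertexType.TASK:
            return ctx.is_executed(src.id)
        return arrived[src.id]

    changed = True
    while changed:
        changed = False
        for vid in model.vertices:
            if vid == start_id or arrived[vid]:
                continue
            incoming = model.in_edges(vid)
            if not incoming:
                continue
            if _is_and_join(model, vid):
                new = all(delivers(e) for e in incoming)
            else:
                new = any(delivers(e) for e in incoming)
            if new:
                arrived[vid] = True
                changed = True
    return arrived


def _kept_graph(
    model: GuidelineModel,
    reach: dict[str, TriState],
    conditions: dict[str, TriState],
) -> nx.DiGraph:
    """Subgraph surviving pruning: reach != FALSE vertices, non-FALSE edges."""
    g = nx.DiGraph()
    g.add_nodes_from(vid for vid in model.vertices
                     if reach[vid] != TriState.FALSE)
    for e in model.edges.values():
        if (conditions[e.id] != TriState.FALSE
                and reach[e.source] != TriState.FALSE
                and reach[e.target] != TriState.FALSE):
            g.add_edge(e.source, e.target)
    return g


def _recurring_vertices(graph: nx.DiGraph) -> set[str]:
    recurring: set[str] = set()
    for scc in nx.strongly_connected_components(graph):
        if len(scc) > 1:
            recurring |= scc
    recurring |= {v for v in graph if graph.has_edge(v, v)}
    return recurring


def can_recur(
    model: GuidelineModel,
    vertex_id: str,
    reach: dict[str, TriState],
    conditions: dict[str, TriState],
) -> bool:
    """True iff the vertex lies on a directed cycle that survives pruning.

    A task that can still be reached again must not be labelled PAST even if
    it was already executed.
    """
    model.vertex(vertex_id)
    if reach[vertex_id] == TriState.FALSE:
        return False
    return vertex_id in _recurring_vertices(_kept_graph(model, reach, conditions))


def assign_roles(model: GuidelineModel, ctx: TreatmentContext) -> RoleAssignment:
    """Infer a temporal role for every vertex, pruning implicitly.

    Task rules: reach FALSE -> pruned; executed and cannot recur -> PAST;
    not executed and arrived -> PRESENT; executed, recurrable and arrived
    again -> PRESENT; otherwise FUTURE.  Events and gateways are structural:
    never PAST, PRESENT iff arrived, else FUTURE (they are excluded from the
    linearized task list but keep internal roles).
    """
    conditions = edge_conditions(model, ctx)
    reach = compute_reach(model, ctx, conditions)
    arrived = compute_arrival(model, ctx, conditions)
    recurring = _recurring_vertices(_kept_graph(model, reach, conditions))

    diagnostics: list[Diagnostic] = []
    roles: dict[str, TemporalRole] = {}
    pruned: set[str] = set()
    for v in model.vertices.values():
        if reach[v.id] == TriState.FALSE:
            pruned.add(v.id)
        elif v.type == VertexType.TASK:
            executed = ctx.is_executed(v.id)
            recurs = v.id in recurring
            if executed and not recurs:
                roles[v.id] = TemporalRole.PAST
            elif arrived[v.id]:
                # not yet executed, or executed but re-enabled on a cycle
                roles[v.id] = TemporalRole.PRESENT
            else:
                roles[v.id] = TemporalRole.FUTURE
        else:
            roles[v.id] = (TemporalRole.PRESENT if arrived[v.id]
                           else TemporalRole.FUTURE)

    # execution records are trusted even when no path delivers control to the
    # task (off-pathway actions happen in real treatments) — but flag them
    for task_id in ctx.executed:
        if task_id in model.vertices and not arrived[task_id]:
            diagnostics.append(Diagnostic(
                Severity.WARNING, "EXECUTED_NOT_DELIVERED",
                f"task {task_id!r} is recorded as executed although no "
                "enabled path delivers control to it", task_id))

    pruned_tasks = [v.id for v in model.vertices.values()
                    if v.id in pruned and v.type == VertexType.TASK]
    return RoleAssignment(roles=roles, pruned=pruned, reach=reach,
                          arrived=arrived, conditions=conditions,
                          diagnostics=diagnostics, pruned_tasks=pruned_tasks)


def prune(model: GuidelineModel, assignment: RoleAssignment) -> GuidelineModel:
    """Subgraph induced by non-pruned vertices.

    Edges whose effective condition evaluated FALSE are removed even between
    surviving vertices.  The start vertex always survives (its reach is TRUE
    by definition).
    """
    kept_vertices = set(assignment.roles)
    kept_edges = {
        e.id for e in model.edges.values()
        if assignment.conditions[e.id] != TriState.FALSE
        and e.source in kept_vertices and e.target in kept_vertices
    }
    return model.subgraph(kept_vertices, kept_edges)
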