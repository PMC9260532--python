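"""Temporal-role inference: reachability, arrival, recurrence, role rules."""

import pytest

from cigpath import (
    GuidelineModel,
    TemporalRole,
    TreatmentContext,
    TriState,
    VertexType,
    assign_roles,
    can_recur,
    compute_arrival,
    compute_reach,
    prune,
)
from cigpath.contextualize import edge_conditions

PAST, PRESENT, FUTURE = TemporalRole.PAST, TemporalRole.PRESENT, TemporalRole.FUTURE


def ctx(executed=None, variables=None):
    return TreatmentContext(executed=executed or {}, variables=variables or {})


# -- reach ------------------------------------------------------------------

def test_reach_false_when_join_condition_fails(sync_fixture):
    # outcome of B rules the join out: everything beyond it is unreachable
    reach = compute_reach(sync_fixture.model, ctx({"A": True, "B": False}))
    assert reach["join"] == TriState.FALSE
    assert reach["C"] == TriState.FALSE
    assert reach["A"] == TriState.TRUE


def test_reach_unknown_when_join_condition_undecided(sync_fixture):
    reach = compute_reach(sync_fixture.model, ctx({"A": True}))
    assert reach["join"] == TriState.UNKNOWN
    assert reach["C"] == TriState.UNKNOWN


def test_reach_all_true_without_conditions(chain_model):
    reach = compute_reach(chain_model, ctx())
    assert set(reach.values()) == {TriState.TRUE}


# -- arrival ----------------------------------------------------------------

def test_arrival_through_synchronizing_join(sync_fixture):
    arrived = compute_arrival(sync_fixture.model, ctx({"A": True, "B": True}))
    assert arrived["join"] and arrived["C"]


def test_arrival_stops_at_unexecuted_tasks(sync_fixture):
    # the parallel split delivers to both branch tasks; nothing beyond
    arrived = compute_arrival(sync_fixture.model, ctx())
    assert arrived["A"] and arrived["B"]
    assert not arrived["join"] and not arrived["C"]


def test_executed_but_undelivered_task_warns():
    # exclusive choice: the context records the task on the ruled-out branch
    m = GuidelineModel(id="xor")
    m.add_vertex("s", VertexType.START)
    m.add_vertex("g", VertexType.XOR_GATEWAY)
    m.add_vertex("T1", VertexType.TASK)
    m.add_vertex("T2", VertexType.TASK)
    m.add_vertex("e1", VertexType.END)
    m.add_vertex("e2", VertexType.END)
    m.add_edge("f1", "s", "g")
    m.add_edge("f2", "g", "T1", condition="X == true")
    m.add_edge("f3", "g", "T2", condition="X == false")
    m.add_edge("f4", "T1", "e1")
    m.add_edge("f5", "T2", "e2")
    a = assign_roles(m, ctx({"T2": True}, {"X": True}))
    assert "T2" in a.pruned  # branch ruled out by X
    assert any(d.code == "EXECUTED_NOT_DELIVERED" and d.element_id == "T2"
               for d in a.diagnostics)
    # but the record is trusted: T2's outgoing edges still deliver
    assert a.arrived["e2"]


# -- recurrence -------------------------------------------------------------

def test_acyclic_task_cannot_recur(chain_model):
    conditions = edge_conditions(chain_model, ctx())
    reach = compute_reach(chain_model, ctx(), conditions)
    assert not can_recur(chain_model, "T1", reach, conditions)


def test_loop_task_recurs_while_repeat_condition_open(loop_model):
    context = ctx({"T1": False})  # repeat condition "T1 == false" holds
    conditions = edge_conditions(loop_model, context)
    reach = compute_reach(loop_model, context, conditions)
    assert can_recur(loop_model, "T1", reach, conditions)


def test_loop_task_cannot_recur_once_back_path_pruned(loop_model):
    context = ctx({"T1": True})  # repeat condition fails: back edge removed
    conditions = edge_conditions(loop_model, context)
    reach = compute_reach(loop_model, context, conditions)
    assert conditions["f4"] == TriState.FALSE
    assert not can_recur(loop_model, "T1", reach, conditions)


def test_loop_roles(loop_model):
    # outcome false: repeat -> T1 is arrived again, exit branch pruned
    a = assign_roles(loop_model, ctx({"T1": False}))
    assert a.roles["T1"] == PRESENT
    assert "T2" in a.pruned
    # outcome true: loop exits -> T1 is done, T2 is the current choice
    a = assign_roles(loop_model, ctx({"T1": True}))
    assert a.roles["T1"] == PAST
    assert a.roles["T2"] == PRESENT
    # no data: T1 is the current choice, T2 possible later
    a = assign_roles(loop_model, ctx())
    assert a.roles["T1"] == PRESENT
    assert a.roles["T2"] == FUTURE


# -- role assignment on the synchronization pattern -------------------------

@pytest.mark.parametrize("case_index, expected", [
    (0, {"A": PAST, "B": PAST, "C": PRESENT}),      # both done successfully
    (4, {"A": PRESENT, "B": PRESENT, "C": FUTURE}),  # nothing recorded yet
    (7, {"A": PAST, "B": PRESENT, "C": None}),       # A failed: C unreachable
])
def test_synchronization_roles(sync_fixture, case_index, expected):
    case = sync_fixture.cases[case_index]
    a = assign_roles(sync_fixture.model, case.context)
    got = {t: a.roles.get(t) for t in ("A", "B", "C")}
    assert got == expected


def test_roles_and_pruned_partition_vertices(sync_fixture, loop_model):
    for model, context in [
        (sync_fixture.model, ctx({"A": True, "B": False})),
        (loop_model, ctx({"T1": False})),
    ]:
        a = assign_roles(model, context)
        assert set(a.roles) | a.pruned == set(model.vertices)
        assert set(a.roles) & a.pruned == set()
        assert all(a.reach[v] == TriState.FALSE for v in a.pruned)
        assert all(a.reach[v] != TriState.FALSE for v in a.roles)


def test_assignment_is_deterministic(sync_fixture):
    context = ctx({"A": True})
    a1 = assign_roles(sync_fixture.model, context)
    a2 = assign_roles(sync_fixture.model, context)
    assert a1.roles == a2.roles
    assert a1.pruned == a2.pruned
    assert a1.reach == a2.reach
    assert a1.arrived == a2.arrived


def test_gateways_and_events_never_past(sync_fixture):
    a = assign_roles(sync_fixture.model, ctx({"A": True, "B": True}))
    for vid, v in sync_fixture.model.vertices.items():
        if v.type != VertexType.TASK and vid in a.roles:
            assert a.roles[vid] in (PRESENT, FUTURE)


def test_chain_role_sequence_property(chain_model):
    """On a pure sequence the roles along the chain always read
    PAST* PRESENT? FUTURE* for every history that executed a prefix."""
    import itertools
    rank = {PAST: 0, PRESENT: 1, FUTURE: 2}
    for k in range(4):
        for values in itertools.product((True, False), repeat=k):
            executed = {f"T{i+1}": v for i, v in enumerate(values)}
            a = assign_roles(chain_model, ctx(executed))
            roles = [a.roles[f"T{i}"] for i in (1, 2, 3)]
            assert [rank[r] for r in roles] == sorted(rank[r] for r in roles)
            assert sum(1 for r in roles if r == PRESENT) <= 1


# -- pruning ----------------------------------------------------------------

def test_prune_drops_failed_join_tail(sync_fixture):
    a = assign_roles(sync_fixture.model, ctx({"A": True, "B": False}))
    sub = prune(sync_fixture.model, a)
    assert set(sub.vertices) == {"start", "split", "A", "B"}
    assert "f5" not in sub.edges  # the failed guard edge
    assert a.pruned_tasks == ["C"]


def test_prune_is_identity_without_conditions(chain_model):
    a = assign_roles(chain_model, ctx())
    sub = prune(chain_model, a)
    assert set(sub.vertices) == set(chain_model.vertices)
    assert set(sub.edges) == set(chain_model.edges)


def test_statically_unreachable_vertex_always_pruned():
    m = GuidelineModel(id="m")
    m.add_vertex("s", VertexType.START)
    m.add_vertex("t", VertexType.TASK)
    m.add_vertex("island", VertexType.TASK)
    m.add_vertex("e", VertexType.END)
    m.add_edge("f1", "s", "t")
    m.add_edge("f2", "t", "e")
    a = assign_roles(m, ctx({"island": True}))
    assert "island" in a.pruned
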