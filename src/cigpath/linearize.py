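"""Linearization of the pruned, role-annotated guideline graph.

The contextualized guideline is presented as a single ordered task list.
Three steps produce it:

1. BFS distances from the start vertex (edge counts).
2. Cycle breaking: while a cycle remains, remove — among all edges lying on
   some cycle — the one farthest from the start, i.e. maximizing the BFS
   distance of its source (ties: larger target distance, then later document
   order).  Because the removed edge (u, v) always satisfies
   dist(v) <= dist(u), no shortest path from the start uses it, so every
   vertex stays start-reachable and the distances remain valid.
3. A modified Kahn topological sort that keeps vertices close to each other
   that are close in the original graph: among ready vertices, prefer a
   direct successor of the most recently emitted vertex, then the smallest
   BFS distance, then the smallest document order.

Only task vertices appear in the final list; events and gateways are
structural scaffolding.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .contextualize import RoleAssignment, TemporalRole
from .errors import CigPathError
from .model import Diagnostic, GuidelineModel, VertexType

__all__ = [
    "Entry",
    "ContextualizedGuideline",
    "bfs_distances",
    "break_cycles",
    "topological_order",
    "linearize",
]


@dataclass(frozen=True)
class Entry:
    task_id: str
    label: str
    role: TemporalRole


@dataclass
class ContextualizedGuideline:
    """Ordered task list plus the record of what was removed to obtain it."""

    entries: list[Entry]
    pruned: list[str]
    removed_edges: list[str]
    diagnostics: list[Diagnostic] = field(default_factory=list)
    # pruned-but-not-yet-sorted graph, for intermediate inspection
    pruned_graph: GuidelineModel | None = None


def bfs_distances(graph: GuidelineModel, start: str) -> dict[str, int]:
    """Shortest-path edge counts from the start vertex.

    Every vertex of a pruned graph is reachable from the start; an
    unreachable vertex here indicates a violated pruning contract.
    """
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for e in graph.out_edges(u):
            if e.target not in dist:
                dist[e.target] = dist[u] + 1
                queue.append(e.target)
    missing = set(graph.vertices) - set(dist)
    if missing:
        raise CigPathError(
            f"vertices unreachable from start after pruning: {sorted(missing)}")
    return dist


def break_cycles(
    graph: GuidelineModel, distances: dict[str, int]
) -> tuple[GuidelineModel, list[str]]:
    """Remove back edges until the graph is acyclic.

    Deterministic regardless of cycle-discovery order: at each step the
    removed edge is the maximum, over *all* edges lying on some cycle, of
    (dist(source), dist(target), document order) — for any particular cycle
    this picks exactly the edge the farthest-from-start rule prescribes.
    Start-reachability of every vertex is preserved (see module docstring).
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.vertices)
    edge_ids: dict[tuple[str, str], list] = {}
    for e in graph.edges.values():
        g.add_edge(e.source, e.target)
        edge_ids.setdefault((e.source, e.target), []).append(e)

    removed: list[str] = []
    while True:
        cyclic_edges = []
        for scc in nx.strongly_connected_components(g):
            if len(scc) > 1:
                cyclic_edges += [(u, v) for u, v in g.edges(scc) if v in scc]
        cyclic_edges += [(v, v) for v in g if g.has_edge(v, v)]
        if not cyclic_edges:
            break
        u, v = max(
            cyclic_edges,
            key=lambda uv: (
                distances[uv[0]],
                distances[uv[1]],
                max(e.order for e in edge_ids[uv]),
            ),
        )
        # parallel edges between the same vertices: drop the latest first
        edge = max(edge_ids[(u, v)], key=lambda e: e.order)
        edge_ids[(u, v)].remove(edge)
        removed.append(edge.id)
        if not edge_ids[(u, v)]:
            g.remove_edge(u, v)

    kept = {eid for eid in graph.edges if eid not in removed}
    return graph.subgraph(set(graph.vertices), kept), removed


def topological_order(
    dag: GuidelineModel,
    distances: dict[str, int],
) -> list[str]:
    """Kahn's algorithm with a locality-preserving ready-set priority.

    Selection among ready (in-degree-zero) vertices: (1) a direct successor
    of the most recently emitted vertex, if any is ready; (2) smallest BFS
    distance; (3) smallest document order.  The result is always a valid
    topological order of the DAG.
    """
    indegree = {vid: dag.in_degree(vid) for vid in dag.vertices}
    ready = {vid for vid, d in indegree.items() if d == 0}
    order_of = {vid: v.order for vid, v in dag.vertices.items()}
    out: list[str] = []
    last: str | None = None
    while ready:
        candidates = ready
        if last is not None:
            succ_ready = {t for t in dag.successors(last) if t in ready}
            if succ_ready:
                candidates = succ_ready
        chosen = min(candidates, key=lambda vid: (distances[vid], order_of[vid]))
        ready.discard(chosen)
        out.append(chosen)
        last = chosen
        for e in dag.out_edges(chosen):
            indegree[e.target] -= 1
            if indegree[e.target] == 0:
                ready.add(e.target)
    if len(out) != len(dag.vertices):
        raise CigPathError("cycle detected during topological sort")
    return out


def linearize(
    pruned_graph: GuidelineModel,
    assignment: RoleAssignment,
    keep_intermediate: bool = False,
) -> ContextualizedGuideline:
    """Compose distances, cycle breaking and the modified Kahn sort, then
    project the vertex order onto tasks with their temporal roles."""
    if pruned_graph.vertices:
        distances = bfs_distances(pruned_graph, pruned_graph.start.id)
        dag, removed = break_cycles(pruned_graph, distances)
        order = topological_order(dag, distances)
    else:
        removed, order = [], []

    entries = [
        Entry(task_id=vid,
              label=pruned_graph.vertices[vid].label,
              role=assignment.roles[vid])
        for vid in order
        if pruned_graph.vertices[vid].type == VertexType.TASK
    ]
    return ContextualizedGuideline(
        entries=entries,
        pruned=list(assignment.pruned_tasks),
        removed_edges=removed,
        diagnostics=list(assignment.diagnostics),
        pruned_graph=pruned_graph if keep_intermediate else None,
    )
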