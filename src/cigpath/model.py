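"""In-memory graph representation of a computer-interpretable guideline (CIG).

A guideline is a directed graph whose vertices are BPMN start/end events,
tasks and gateways, and whose edges are sequence flows optionally guarded by
a condition expression.  Document order of every element in the source file
is recorded and used as the universal deterministic tie-breaker throughout
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ModelLookupError

__all__ = [
    "VertexType",
    "Vertex",
    "Edge",
    "GuidelineModel",
    "Diagnostic",
    "Severity",
    "validate_model",
]


class VertexType(Enum):
    START = "start"
    END = "end"
    TASK = "task"
    XOR_GATEWAY = "xor_gateway"
    AND_GATEWAY = "and_gateway"

    @property
    def is_gateway(self) -> bool:
        return self in (VertexType.XOR_GATEWAY, VertexType.AND_GATEWAY)


@dataclass(frozen=True)
class Vertex:
    id: str
    type: VertexType
    label: str = ""
    order: int = 0


@dataclass(frozen=True)
class Edge:
    id: str
    source: str
    target: str
    condition: str | None = None
    order: int = 0


class Severity(Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Diagnostic:
    severity: Severity
    code: str
    message: str
    element_id: str | None = None


@dataclass
class GuidelineModel:
    """A validated-or-validatable guideline graph.

    Vertices and edges are kept in insertion (document) order; structural
    queries return neighbours sorted by edge document order.
    """

    id: str
    vertices: dict[str, Vertex] = field(default_factory=dict)
    edges: dict[str, Edge] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    def add_vertex(self, id: str, type: VertexType, label: str = "") -> Vertex:
        if id in self.vertices:
            raise ValueError(f"duplicate vertex id {id!r}")
        v = Vertex(id=id, type=type, label=label or id, order=len(self.vertices))
        self.vertices[id] = v
        return v

    def add_edge(
        self, id: str, source: str, target: str, condition: str | None = None
    ) -> Edge:
        if id in self.edges:
            raise ValueError(f"duplicate edge id {id!r}")
        e = Edge(id=id, source=source, target=target, condition=condition,
                 order=len(self.edges))
        self.edges[id] = e
        return e

    # -- structural queries ---------------------------------------------------

    def vertex(self, vertex_id: str) -> Vertex:
        try:
            return self.vertices[vertex_id]
        except KeyError:
            raise ModelLookupError(f"unknown vertex id {vertex_id!r}") from None

    def in_edges(self, vertex_id: str) -> list[Edge]:
        self.vertex(vertex_id)
        return sorted((e for e in self.edges.values() if e.target == vertex_id),
                      key=lambda e: e.order)

    def out_edges(self, vertex_id: str) -> list[Edge]:
        self.vertex(vertex_id)
        return sorted((e for e in self.edges.values() if e.source == vertex_id),
                      key=lambda e: e.order)

    def predecessors(self, vertex_id: str) -> list[str]:
        return [e.source for e in self.in_edges(vertex_id)]

    def successors(self, vertex_id: str) -> list[str]:
        return [e.target for e in self.out_edges(vertex_id)]

    def in_degree(self, vertex_id: str) -> int:
        return len(self.in_edges(vertex_id))

    def out_degree(self, vertex_id: str) -> int:
        return len(self.out_edges(vertex_id))

    @property
    def start(self) -> Vertex:
        starts = [v for v in self.vertices.values() if v.type == VertexType.START]
        if len(starts) != 1:
            raise ModelLookupError(
                f"model has {len(starts)} start vertices, expected exactly 1")
        return starts[0]

    def tasks(self) -> list[Vertex]:
        return [v for v in self.vertices.values() if v.type == VertexType.TASK]

    def reachable_from_start(self) -> set[str]:
        """Vertex ids on some directed path from the start vertex."""
        starts = [v.id for v in self.vertices.values() if v.type == VertexType.START]
        seen: set[str] = set(starts)
        frontier = list(starts)
        while frontier:
            u = frontier.pop()
            for e in self.out_edges(u):
                # dangling targets are reported by validate_model separately
                if e.target in self.vertices and e.target not in seen:
                    seen.add(e.target)
                    frontier.append(e.target)
        return seen

    def subgraph(self, vertex_ids: set[str], edge_ids: set[str]) -> "GuidelineModel":
        """Induced sub-model preserving ids, labels and document order."""
        sub = GuidelineModel(id=self.id)
        sub.vertices = {vid: v for vid, v in self.vertices.items() if vid in vertex_ids}
        sub.edges = {
            eid: e for eid, e in self.edges.items()
            if eid in edge_ids and e.source in vertex_ids and e.target in vertex_ids
        }
        return sub


def validate_model(model: GuidelineModel) -> list[Diagnostic]:
    """Check structural well-formedness; returns every violation found.

    The model is never mutated.  An empty list means the model satisfies all
    invariants: exactly one start event with in-degree 0, end events with
    out-degree 0, gateways that either split or join but not both, edge
    endpoints that exist, no self-loops on non-task vertices.  Vertices not
    on any path from the start are reported as warnings (they are pruned
    unconditionally by contextualization).
    """
    diags: list[Diagnostic] = []

    for e in model.edges.values():
        for endpoint, role in ((e.source, "source"), (e.target, "target")):
            if endpoint not in model.vertices:
                diags.append(Diagnostic(
                    Severity.ERROR, "UNKNOWN_VERTEX",
                    f"edge {e.id!r} {role} {endpoint!r} does not exist", e.id))
        if (e.source == e.target and e.source in model.vertices
                and model.vertices[e.source].type != VertexType.TASK):
            diags.append(Diagnostic(
                Severity.ERROR, "SELF_LOOP",
                f"self-loop on non-task vertex {e.source!r}", e.id))

    starts = [v for v in model.vertices.values() if v.type == VertexType.START]
    if not starts:
        diags.append(Diagnostic(Severity.ERROR, "NO_START",
                                "model has no start event", None))
    elif len(starts) > 1:
        diags.append(Diagnostic(
            Severity.ERROR, "MULTIPLE_START",
            f"model has {len(starts)} start events", starts[1].id))
    for v in starts:
        if any(e.target == v.id for e in model.edges.values()):
            diags.append(Diagnostic(
                Severity.ERROR, "START_INCOMING",
                f"start event {v.id!r} has incoming sequence flows", v.id))

    for v in model.vertices.values():
        indeg = sum(1 for e in model.edges.values() if e.target == v.id)
        outdeg = sum(1 for e in model.edges.values() if e.source == v.id)
        if v.type == VertexType.END and outdeg > 0:
            diags.append(Diagnostic(
                Severity.ERROR, "END_OUTGOING",
                f"end event {v.id!r} has outgoing sequence flows", v.id))
        if v.type.is_gateway:
            if indeg > 1 and outdeg > 1:
                diags.append(Diagnostic(
                    Severity.ERROR, "MIXED_GATEWAY",
                    f"gateway {v.id!r} both joins (in={indeg}) and splits "
                    f"(out={outdeg}); mixed gateways are not supported", v.id))
            elif indeg <= 1 and outdeg <= 1:
                diags.append(Diagnostic(
                    Severity.ERROR, "GATEWAY_DEGREE",
                    f"gateway {v.id!r} neither joins nor splits "
                    f"(in={indeg}, out={outdeg})", v.id))

    if len(starts) >= 1:
        reachable = model.reachable_from_start()
        for v in model.vertices.values():
            if v.id not in reachable:
                diags.append(Diagnostic(
                    Severity.WARNING, "UNREACHABLE_VERTEX",
                    f"vertex {v.id!r} lies on no path from the start event; "
                    "it will be pruned from every contextualization", v.id))

    return diags
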