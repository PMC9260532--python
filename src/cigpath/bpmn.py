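"""Reading the supported BPMN 2.0 subset and serializing results.

Only the elements needed for guideline procedure models are supported:
plain start/end events, tasks (all task subtypes collapse to TASK),
exclusive and parallel gateways, and sequence flows with optional condition
expressions.  Diagram-interchange information is ignored.  Condition
expressions are stored verbatim (whitespace-trimmed) and interpreted by
:mod:`cigpath.conditions`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from lxml import etree

from .conditions import TreatmentContext
from .errors import BpmnParseError, ContextError, UnsupportedElementError, UsageError
from .model import Diagnostic, GuidelineModel, Severity, VertexType

if TYPE_CHECKING:
    from .linearize import ContextualizedGuideline

__all__ = [
    "BPMN_NS",
    "BpmnDialectOptions",
    "parse_bpmn",
    "read_context",
    "write_contextualized",
]

BPMN_NS = "http://www.omg.org/spec/BPMN/20100524/MODEL"

_VERTEX_TAGS = {
    "startEvent": VertexType.START,
    "endEvent": VertexType.END,
    "task": VertexType.TASK,
    "userTask": VertexType.TASK,
    "serviceTask": VertexType.TASK,
    "manualTask": VertexType.TASK,
    "exclusiveGateway": VertexType.XOR_GATEWAY,
    "parallelGateway": VertexType.AND_GATEWAY,
}

# process-level children that carry no flow semantics for us
_IGNORED_TAGS = {"documentation", "extensionElements", "laneSet"}


@dataclass
class BpmnDialectOptions:
    """lenient=True skips unsupported elements with a warning instead of
    failing."""

    lenient: bool = False
    namespace: str = BPMN_NS


def _localname(element) -> str | None:
    qname = etree.QName(element)
    return qname.localname if qname.namespace == BPMN_NS else None


def parse_bpmn(
    xml_text: str | bytes,
    options: BpmnDialectOptions | None = None,
    diagnostics: list[Diagnostic] | None = None,
) -> GuidelineModel:
    """Parse BPMN 2.0 XML into a :class:`GuidelineModel`.

    The document must contain exactly one ``process``.  Vertex and edge
    ``order`` fields follow document order.  Unsupported flow elements raise
    :class:`UnsupportedElementError` unless ``options.lenient``.
    """
    options = options or BpmnDialectOptions()
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise BpmnParseError(f"malformed XML: {exc}") from exc

    processes = root.findall(f".//{{{BPMN_NS}}}process")
    if _localname(root) == "process":
        processes = [root] + processes
    if len(processes) != 1:
        raise BpmnParseError(
            f"expected exactly one process definition, found {len(processes)}")
    process = processes[0]

    model = GuidelineModel(id=process.get("id") or "process")
    flows = []  # (element, position) collected first so edges follow vertices
    for child in process:
        if not isinstance(child.tag, str):  # comments, processing instructions
            continue
        tag = _localname(child)
        if tag is None or tag in _IGNORED_TAGS:
            continue
        if tag == "sequenceFlow":
            flows.append(child)
            continue
        vtype = _VERTEX_TAGS.get(tag)
        if vtype is None:
            if options.lenient:
                if diagnostics is not None:
                    diagnostics.append(Diagnostic(
                        Severity.WARNING, "UNSUPPORTED_ELEMENT",
                        f"skipping unsupported element <{tag}>",
                        child.get("id")))
                continue
            raise UnsupportedElementError(tag, child.get("id"))
        # events with event definitions (timer, message, ...) are out of scope
        defs = [g for g in child
                if isinstance(g.tag, str)
                and (_localname(g) or "").endswith("EventDefinition")]
        if defs:
            def_tag = _localname(defs[0])
            if not options.lenient:
                raise UnsupportedElementError(def_tag, child.get("id"))
            if diagnostics is not None:
                diagnostics.append(Diagnostic(
                    Severity.WARNING, "UNSUPPORTED_ELEMENT",
                    f"ignoring <{def_tag}> on {child.get('id')!r}",
                    child.get("id")))
        vid = child.get("id")
        if not vid:
            raise BpmnParseError(f"<{tag}> element without id")
        model.add_vertex(vid, vtype, label=child.get("name") or vid)

    for flow in flows:
        eid = flow.get("id")
        source = flow.get("sourceRef")
        target = flow.get("targetRef")
        if not (eid and source and target):
            raise BpmnParseError(
                f"sequenceFlow {eid!r} missing id/sourceRef/targetRef")
        condition = None
        for child in flow:
            if isinstance(child.tag, str) and _localname(child) == "conditionExpression":
                text = (child.text or "").strip()
                condition = text or None
        model.add_edge(eid, source, target, condition=condition)

    return model


# --------------------------------------------------------------------------
# Context JSON
# --------------------------------------------------------------------------

def read_context(
    json_text: str,
    diagnostics: list[Diagnostic] | None = None,
) -> TreatmentContext:
    """Read a treatment context from JSON.

    Schema: an object with optional keys ``executed`` (task id -> recorded
    scalar outcome) and ``variables`` (name -> scalar).  Unknown top-level
    keys produce a warning; non-scalar values are an error.
    """
    try:
        payload = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ContextError(f"context is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise ContextError("context must be a JSON object")
    for key in payload:
        if key not in ("executed", "variables"):
            if diagnostics is not None:
                diagnostics.append(Diagnostic(
                    Severity.WARNING, "UNKNOWN_CONTEXT_KEY",
                    f"ignoring unknown top-level key {key!r}", None))
    for key in ("executed", "variables"):
        if key in payload and not isinstance(payload[key], dict):
            raise ContextError(f"context key {key!r} must be an object")
    return TreatmentContext.from_mappings(
        payload.get("executed"), payload.get("variables"))


def write_context(ctx: TreatmentContext) -> str:
    """Serialize a treatment context back to its JSON wire form."""
    return json.dumps(
        {"executed": dict(ctx.executed), "variables": dict(ctx.variables)},
        indent=2) + "\n"


# --------------------------------------------------------------------------
# Result serialization
# --------------------------------------------------------------------------

def write_contextualized(cg: "ContextualizedGuideline", format: str = "json") -> str:
    """Serialize a contextualized guideline deterministically.

    Identical inputs yield byte-identical output: key order is fixed and no
    timestamps or environment data are embedded.
    """
    if format == "json":
        doc = {
            "entries": [
                {"taskId": e.task_id, "label": e.label, "role": e.role.value}
                for e in cg.entries
            ],
            "pruned": list(cg.pruned),
            "removedEdges": list(cg.removed_edges),
            "diagnostics": [
                {"severity": d.severity.value, "code": d.code,
                 "message": d.message, "elementId": d.element_id}
                for d in cg.diagnostics
            ],
        }
        return json.dumps(doc, indent=2) + "\n"
    if format == "tsv":
        lines = ["taskId\tlabel\trole"]
        lines += [f"{e.task_id}\t{e.label}\t{e.role.value}" for e in cg.entries]
        lines += [f"{tid}\t\tpruned" for tid in cg.pruned]
        return "\n".join(lines) + "\n"
    raise UsageError(f"unknown output format {format!r} (expected json or tsv)")
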