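"""Stateless HTTP facade.

Routes:

* ``POST /guidelines`` — body: BPMN XML; stores the parsed model under a
  content-hash id and returns ``{"guidelineId": ...}`` (re-posting the same
  model is idempotent).
* ``GET /guidelines/{id}`` — echo of the stored model structure.
* ``POST /guidelines/{id}/contextualize`` — body: context JSON; returns the
  contextualized guideline.  No patient state persists between calls: the
  entire inference is redone per request.

The registry of posted models is in-memory only; guideline models are
design-time artifacts, patient data never touches the registry.
"""

from __future__ import annotations

import hashlib
import json
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .bpmn import parse_bpmn, read_context, write_contextualized
from .errors import CigPathError
from .model import GuidelineModel
from .pipeline import ValidationFailure, contextualize_model

__all__ = ["GuidelineRegistry", "make_server", "run_server"]


class GuidelineRegistry:
    """In-memory store of parsed guideline models keyed by content hash."""

    def __init__(self) -> None:
        self._models: dict[str, GuidelineModel] = {}

    def put(self, xml_text: str) -> str:
        guideline_id = hashlib.sha256(xml_text.encode("utf-8")).hexdigest()[:16]
        if guideline_id not in self._models:
            self._models[guideline_id] = parse_bpmn(xml_text)
        return guideline_id

    def get(self, guideline_id: str) -> GuidelineModel | None:
        return self._models.get(guideline_id)


def _model_echo(model: GuidelineModel) -> dict:
    return {
        "id": model.id,
        "vertices": [
            {"id": v.id, "type": v.type.value, "label": v.label}
            for v in sorted(model.vertices.values(), key=lambda v: v.order)
        ],
        "edges": [
            {"id": e.id, "source": e.source, "target": e.target,
             "condition": e.condition}
            for e in sorted(model.edges.values(), key=lambda e: e.order)
        ],
    }


def make_server(host: str = "127.0.0.1", port: int = 0) -> ThreadingHTTPServer:
    registry = GuidelineRegistry()

    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args) -> None:  # quiet by default
            pass

        def _send(self, status: int, payload: dict | str) -> None:
            body = (payload if isinstance(payload, str)
                    else json.dumps(payload, indent=2) + "\n").encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _body(self) -> str:
            length = int(self.headers.get("Content-Length") or 0)
            return self.rfile.read(length).decode("utf-8")

        def do_POST(self) -> None:  # noqa: N802 - http.server API
            parts = [p for p in self.path.split("/") if p]
            try:
                if parts == ["guidelines"]:
                    guideline_id = registry.put(self._body())
                    self._send(200, {"guidelineId": guideline_id})
                elif (len(parts) == 3 and parts[0] == "guidelines"
                        and parts[2] == "contextualize"):
                    model = registry.get(parts[1])
                    if model is None:
                        self._send(404, {"error": f"unknown guideline {parts[1]!r}"})
                        return
                    ctx = read_context(self._body())
                    cg = contextualize_model(model, ctx)
                    self._send(200, write_contextualized(cg, "json"))
                else:
                    self._send(404, {"error": f"no such route {self.path!r}"})
            except ValidationFailure as exc:
                self._send(400, {"error": str(exc), "diagnostics": [
                    {"severity": d.severity.value, "code": d.code,
                     "message": d.message} for d in exc.diagnostics]})
            except CigPathError as exc:
                self._send(400, {"error": str(exc)})

        def do_GET(self) -> None:  # noqa: N802
            parts = [p for p in self.path.split("/") if p]
            if len(parts) == 2 and parts[0] == "guidelines":
                model = registry.get(parts[1])
                if model is None:
                    self._send(404, {"error": f"unknown guideline {parts[1]!r}"})
                else:
                    self._send(200, _model_echo(model))
            else:
                self._send(404, {"error": f"no such route {self.path!r}"})

    return ThreadingHTTPServer((host, port), Handler)


def run_server(host: str = "127.0.0.1", port: int = 8080) -> None:
    server = make_server(host, port)
    try:
        server.serve_forever()
    finally:
        server.server_close()
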