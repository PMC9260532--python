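"""End-to-end contextualization: validate -> infer roles -> prune -> linearize."""

from __future__ import annotations

from .conditions import TreatmentContext
from .contextualize import assign_roles, prune
from .errors import CigPathError
from .linearize import ContextualizedGuideline, linearize
from .model import Diagnostic, GuidelineModel, Severity, validate_model

__all__ = ["ValidationFailure", "contextualize_model"]


class ValidationFailure(CigPathError):
    """The model violates structural invariants; carries the diagnostics."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        messages = "; ".join(f"{d.code}: {d.message}" for d in diagnostics)
        super().__init__(f"model failed validation: {messages}")


def contextualize_model(
    model: GuidelineModel,
    ctx: TreatmentContext,
    keep_intermediate: bool = False,
) -> ContextualizedGuideline:
    """Full stateless pipeline for one (model, context) pair.

    Raises :class:`ValidationFailure` when the model has error-level
    diagnostics; warnings (e.g. statically unreachable vertices) are carried
    through into the result's diagnostics list.
    """
    diags = validate_model(model)
    errors = [d for d in diags if d.severity == Severity.ERROR]
    if errors:
        raise ValidationFailure(errors)
    assignment = assign_roles(model, ctx)
    pruned_graph = prune(model, assignment)
    cg = linearize(pruned_graph, assignment, keep_intermediate=keep_intermediate)
    cg.diagnostics = [d for d in diags if d.severity == Severity.WARNING] \
        + cg.diagnostics
    return cg
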