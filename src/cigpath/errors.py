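"""Exception hierarchy.

Diagnostics (validation findings, warnings) are data, not exceptions; see
:mod:`cigpath.model`.  Exceptions are reserved for contract violations that
make the requested computation impossible.
"""


class CigPathError(Exception):
    """Base class for all package errors."""


class BpmnParseError(CigPathError):
    """The input is not well-formed XML or not a usable BPMN process."""


class UnsupportedElementError(BpmnParseError):
    """A BPMN element outside the supported subset was encountered (strict mode)."""

    def __init__(self, tag: str, element_id: str | None = None):
        self.tag = tag
        self.element_id = element_id
        suffix = f" (id={element_id})" if element_id else ""
        super().__init__(f"unsupported BPMN element <{tag}>{suffix}")


class ContextError(CigPathError):
    """The treatment-context JSON violates its schema."""


class ModelLookupError(CigPathError, KeyError):
    """A vertex or edge id does not exist in the model."""


class ExpressionSyntaxError(CigPathError):
    """A condition expression could not be parsed."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} at position {position}")


class EvaluationError(CigPathError):
    """A condition expression is ill-typed for the given context."""


class OracleScaleError(CigPathError):
    """The brute-force oracle refuses: too many unknowns to enumerate."""


class UsageError(CigPathError):
    """Invalid arguments to a user-facing operation."""
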