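"""Exception and warning types used across the package."""


class ClinDeclareError(Exception):
    """Base class for all package errors."""


class LogInputError(ClinDeclareError):
    """Malformed tabular/XES input for an event log (bad timestamp, missing case id, ...)."""


class StructuralError(ClinDeclareError):
    """An in-memory object violates a structural invariant (e.g. event without any time)."""


class XesParseError(ClinDeclareError):
    """The XES document could not be parsed or lacks required elements."""


class ConditionParseError(ClinDeclareError):
    """A data-condition string does not match the bracket grammar."""


class ModelError(ClinDeclareError):
    """A process-model file or object fails validation."""


class ClinDeclareWarning(UserWarning):
    """Base warning (unmapped attribute kinds, unknown activities, ...)."""
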