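"""Exception hierarchy for the pipeline.

Validation failures that name a schema problem raise :class:`SchemaError`;
cross-table key problems raise :class:`ReferentialError`. Both derive from
:class:`GTTError` so callers can catch everything the pipeline raises.
"""


class GTTError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(GTTError):
    """A file or frame does not match the declared schema (e.g. missing column)."""


class ReferentialError(GTTError):
    """A child row references an admission_id absent from the admissions table."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = rows if rows is not None else []


class ValidationError(GTTError):
    """A value violates a domain invariant (vocabulary, range, ordering)."""


class ConfigurationError(GTTError):
    """A registry or run configuration is malformed."""


class ComputationError(GTTError):
    """A statistical computation cannot proceed (empty group, zero denominator)."""


class GenerationError(GTTError):
    """The synthetic generator produced data inconsistent with its ground truth."""
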