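"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`SmmdaError`, so callers (and the
CLI) can surface the failing stage without pattern-matching on messages.
"""


class SmmdaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SmmdaError):
    """Invalid or inconsistent configuration (bad columns, bad widths...)."""


class EmptyInputError(SmmdaError):
    """An input that must be non-empty was empty."""


class DataValidationError(SmmdaError):
    """Input data violates a structural contract (grammar, symmetry...)."""


class DegenerateInputError(SmmdaError):
    """Input is formally valid but makes the requested quantity undefined."""


class AlignmentError(SmmdaError):
    """Two labelled matrices that must share an index do not."""


class EntityLookupError(SmmdaError, KeyError):
    """A named miRNA/disease is absent from the relevant index."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep messages readable
        return Exception.__str__(self)


class CapacityError(SmmdaError):
    """A sampling request exceeds what the data can provide."""


class InvalidDAGError(DataValidationError):
    """A disease graph that must be acyclic contains a cycle."""
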