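"""Exception hierarchy."""


class PairscapeError(Exception):
    """Base class for all package errors."""


class StructuralInputError(PairscapeError):
    """A structure is missing atoms or violates a structural precondition."""


class FitError(PairscapeError):
    """A least-squares superposition is degenerate."""


class ContractError(PairscapeError):
    """An input object violates its declared invariants."""


class SelectionError(PairscapeError):
    """An atom/residue selection cannot be resolved or is empty."""


class ConfigurationError(PairscapeError):
    """A configuration value is missing, unknown or inconsistent."""


class CatalogError(PairscapeError):
    """An unknown sequence class or system was requested."""


class ParseError(PairscapeError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConditioningError(PairscapeError):
    """A covariance matrix stayed non-positive-definite after jitter."""


class MaskedValueError(PairscapeError):
    """A value was requested inside an insufficiently sampled region."""
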