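"""Exception hierarchy shared across the pipeline stages."""


class TransmapError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(TransmapError, ValueError):
    """An argument violates a documented precondition."""


class SimulationError(TransmapError, RuntimeError):
    """A stochastic generator could not satisfy its contract
    (e.g. a case/control quota unreachable within the draw cap)."""


class DataError(TransmapError, ValueError):
    """Input data are structurally valid but unusable
    (no shared variants, undefined LD, single phenotype class...)."""


class FormatError(TransmapError, ValueError):
    """A file does not conform to its documented format.

    Carries the offending line number when one is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CapacityError(TransmapError, ValueError):
    """A request exceeds the exhaustive-enumeration bound."""
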