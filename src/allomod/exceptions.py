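"""Exception hierarchy shared across the package."""


class AllomodError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AllomodError):
    """A parameter or input value violates a documented invariant.

    Carries the offending field name so batch callers can report precisely.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class TopologyError(AllomodError):
    """Scheme configuration inconsistent with the chosen binding topology."""


class ConfigurationError(AllomodError):
    """A scheme or run configuration is structurally invalid."""


class StructureError(AllomodError):
    """The state graph is disconnected or otherwise rank-deficient."""


class ConvergenceError(AllomodError):
    """An iterative solve failed to reach tolerance within its horizon."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class FitRefusedError(AllomodError):
    """A replicate does not meet the minimum requirements for fitting."""


class AggregationError(AllomodError):
    """Too few converged fits to summarise."""


class PairingError(AllomodError):
    """Paired analysis requested on replicates that cannot be matched."""


class AnalysisError(AllomodError):
    """A composite analysis failed; message names the offending stage."""


class NoAssociationError(AnalysisError):
    """Observed relaxation rates do not increase with concentration."""


class ParseError(AllomodError):
    """A delimited-text table violates its schema."""
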