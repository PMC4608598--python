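"""Exception hierarchy for antioxkit.

Every error raised by the package derives from :class:`AntioxkitError`, so
callers (and the CLI) can distinguish data problems (exit code 2) from fit
failures (exit code 3) with two ``except`` clauses.
"""


class AntioxkitError(Exception):
    """Base class for all antioxkit errors."""


class SchemaError(AntioxkitError):
    """A required column or key is missing or misnamed."""


class ValidationError(AntioxkitError):
    """Data violates a structural invariant (duplicate keys, bad series...)."""


class DomainError(AntioxkitError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateControlError(DomainError):
    """The control shows no effect, so a ratio to it is undefined."""


class InsufficientDataError(AntioxkitError):
    """Too few points to perform the requested estimate."""


class FitError(AntioxkitError):
    """A nonlinear fit failed to converge.

    ``diagnostics`` carries whatever the optimiser reported, for display.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class KineticFitError(FitError):
    """A kinetic (time-course) fit diverged."""


class ProOxidantWarning(UserWarning):
    """A corrected absorbance or response is negative: the compound promotes,
    rather than inhibits, oxidative degradation in this assay system."""
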