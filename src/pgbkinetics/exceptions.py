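"""Exception hierarchy shared by all stages of the analysis."""


class PgbKineticsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PgbKineticsError, ValueError):
    """A rate constant, concentration, or flag violates its contract."""


class DegenerateEquilibriumError(InvalidParameterError):
    """A forward rate is nonzero while its backward rate is zero, so the
    corresponding equilibrium (and any state split derived from it) is undefined."""


class IntegrationError(PgbKineticsError, RuntimeError):
    """The stiff integrator failed; carries the time at which it gave up."""

    def __init__(self, message: str, time_of_failure: float | None = None):
        super().__init__(message)
        self.time_of_failure = time_of_failure


class ParseError(PgbKineticsError, ValueError):
    """A delimited-text or key-value file is malformed; carries the line number."""

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        loc = f"{path or '<input>'}:{line}" if line is not None else (path or "<input>")
        super().__init__(f"{loc}: {message}")
        self.line = line
        self.path = path


class InvalidRecipeError(PgbKineticsError, ValueError):
    """A synthetic-spectra recipe is unusable (e.g. collinear basis spectra)."""
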