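"""Exception hierarchy."""


class RibopinchError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(RibopinchError):
    """Too few observations to identify the requested model."""


class DegenerateDataError(RibopinchError):
    """Data carry no signal for the requested model (e.g. no decay)."""


class FitError(RibopinchError):
    """Optimizer failed to converge; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ValidationError(RibopinchError):
    """Input violated a type invariant (bad table, bad duplex, bad units)."""


class SchemaError(ValidationError):
    """A delimited input file is missing required columns or has bad rows."""

    def __init__(self, message: str, path=None, column=None, row=None):
        super().__init__(message)
        self.path, self.column, self.row = path, column, row


class ParameterTableError(RibopinchError):
    """Nearest-neighbor parameter table incomplete or inconsistent."""


class ConfigError(RibopinchError):
    """Invalid or incomplete configuration."""


class GroupingError(RibopinchError):
    """Records grouped for a joint fit have incompatible conditions."""


class SaturationWarning(UserWarning):
    """Titration data approach saturation; a log-log slope underestimates n."""
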