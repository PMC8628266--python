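"""Exception hierarchy shared across the pipeline."""


class RitPipeError(Exception):
    """Base class for all pipeline errors."""


class UnknownNuclideError(RitPipeError, KeyError):
    """Requested nuclide is not present in the registry."""


class MissingConstantError(RitPipeError, ValueError):
    """A nuclide lacks a physical constant required by the operation."""


class ValidationError(RitPipeError, ValueError):
    """Input data violates a domain invariant."""


class TableParseError(ValidationError):
    """A tabular input could not be parsed; carries row/column context."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        ctx = []
        if row is not None:
            ctx.append(f"row {row}")
        if column is not None:
            ctx.append(f"column {column!r}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.row = row
        self.column = column


class ConfigError(RitPipeError, ValueError):
    """A run / module configuration value is invalid."""
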