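"""Exception types shared across the package."""


class NitrosipError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NitrosipError, ValueError):
    """A domain object or parameter violates its invariants."""


class SchemaError(NitrosipError, ValueError):
    """An input table or file does not match the expected schema.

    Carries optional row/line context so malformed inputs can be
    reported precisely.
    """

    def __init__(self, message: str, *, line: int | None = None,
                 column: str | None = None):
        ctx = []
        if line is not None:
            ctx.append(f"line {line}")
        if column is not None:
            ctx.append(f"column {column!r}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.line = line
        self.column = column


class ConfigError(NitrosipError, ValueError):
    """A run configuration is invalid (unknown key, out-of-domain value)."""
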