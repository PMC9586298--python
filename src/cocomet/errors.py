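"""Exception hierarchy shared across the package."""


class CocometError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CocometError):
    """A generator or pipeline setting is invalid (non-positive size, unknown key...)."""


class ValidationError(CocometError):
    """Parsed data violates an invariant (duplicate id, negative area, bad genotype...)."""


class DimensionError(ValidationError):
    """Two objects that must share an axis (samples, features, genes) do not."""


class ParseError(CocometError):
    """A file cell could not be interpreted; carries file/line context when known."""

    def __init__(self, message: str, path=None, line=None):
        ctx = []
        if path is not None:
            ctx.append(str(path))
        if line is not None:
            ctx.append(f"line {line}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.path = path
        self.line = line
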