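"""Exception types shared across the package."""


class XmodalError(Exception):
    """Base class for package errors."""


class ConfigError(XmodalError):
    """A configuration field is invalid.  The message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field {field!r}: {message}")


class StructuralError(XmodalError):
    """Input data violate a structural precondition (missing blocks, columns...)."""


class IngestionError(XmodalError):
    """An external file could not be mapped onto the package's data model."""
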