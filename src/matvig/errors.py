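"""Exception types shared across the engine."""


class MatvigError(Exception):
    """Base class for engine errors."""


class SchemaError(MatvigError):
    """Input file does not satisfy the declared schema map (e.g. missing
    mandatory columns)."""


class StructuralError(MatvigError):
    """Geographic hierarchy is malformed (orphan unit, cycle, bad level)."""


class ConfigError(MatvigError):
    """Invalid or missing configuration."""


class DomainError(MatvigError):
    """A scalar argument is outside its mathematical domain."""
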