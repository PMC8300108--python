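"""Error hierarchy.

Every error carries a short machine-readable ``category`` so the CLI can
report failures in a scriptable form (``error:<category>: message``).
"""


class EKSSError(Exception):
    """Base class for all package errors."""

    category = "general"


class ValidationError(EKSSError):
    """Invalid input value (out-of-range score, negative quantity, ...)."""

    category = "validation"


class ConfigError(EKSSError):
    """Malformed configuration (bad bounds, unknown keys, ...)."""

    category = "config"


class SchemaError(EKSSError):
    """Input table does not match the expected schema."""

    category = "schema"
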