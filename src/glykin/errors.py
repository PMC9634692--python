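"""Exception hierarchy shared across the package.

All input-validation failures derive from :class:`GlykinError` so callers can
catch one base class; they also derive from the matching builtin
(``ValueError``/``RuntimeError``) so untyped callers fail conventionally.
"""


class GlykinError(Exception):
    """Base class for all package-specific errors."""


class InputDomainError(GlykinError, ValueError):
    """An argument violates a mathematical or physical precondition."""


class DataError(GlykinError, ValueError):
    """Observed data violate the schema or a data-domain requirement."""


class InsufficientDataError(DataError):
    """Too few usable points remain to perform the requested fit."""


class ConfigurationError(GlykinError, ValueError):
    """A run configuration or band map is inconsistent."""


class ComputationError(GlykinError, RuntimeError):
    """A numerical procedure failed to produce a trustworthy result."""
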