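"""Exception hierarchy shared across the package."""


class MeldAllocError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MeldAllocError, ValueError):
    """A value violates a domain invariant (non-positive lab, bad region, ...)."""


class SchemaError(MeldAllocError, ValueError):
    """A registry file is missing mandatory columns or is otherwise unreadable."""


class DegenerateInputError(MeldAllocError, ValueError):
    """An estimator was handed input it cannot act on (empty group, no events, ...)."""


class ConfigError(MeldAllocError, ValueError):
    """A simulation or model configuration is internally inconsistent."""
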