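"""Exception hierarchy shared across the pipeline."""


class CoretransError(Exception):
    """Base class for all package errors."""


class FormatError(CoretransError, ValueError):
    """An input file does not follow the expected tabular layout."""


class EmptyInputError(CoretransError, ValueError):
    """An input carries no usable records."""


class ValidationError(CoretransError, ValueError):
    """A domain invariant is violated (duplicate ids, bad ranges, ...)."""


class BackendError(CoretransError, RuntimeError):
    """A community-detection backend is unavailable or misconfigured."""


class ConfigError(CoretransError, ValueError):
    """A pipeline configuration is incomplete or inconsistent."""
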