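"""Exception types shared across the package."""


class GazepredError(Exception):
    """Base class for all package errors."""


class ParameterError(GazepredError, ValueError):
    """An argument is outside its documented domain."""


class FormatError(GazepredError, ValueError):
    """A delimited-text file violates its schema; message names the row."""


class AlignmentError(GazepredError, ValueError):
    """Vectors/tables that must be aligned to corpus tokens are not."""


class DegenerateCacheError(GazepredError, ZeroDivisionError):
    """Cache probability requested with delta = 0 and an empty cache."""


class DependencyError(GazepredError, RuntimeError):
    """A pipeline stage was requested without its upstream artifacts."""


class SpecError(GazepredError, ValueError):
    """A model specification references unknown columns or is not nested."""
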