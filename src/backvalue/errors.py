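"""Exception hierarchy.

Every error raised by the package derives from :class:`BackValueError`, so
callers can catch one type at a pipeline boundary while tests can assert on
the specific failure mode.
"""


class BackValueError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BackValueError):
    """A simulation or pipeline configuration field is invalid."""


class InputError(BackValueError):
    """A caller-supplied argument or file is invalid (bad year label,
    decile outside 1..10, negative count, missing column, ...)."""


class DataIntegrityError(BackValueError):
    """Two inputs that must be consistent are not (e.g. an episode refers
    to a practice absent from the registers, or a stratum has events but a
    zero denominator)."""


class PlanInfeasibleError(BackValueError):
    """A reallocation plan spends more than the available budget; the
    message reports the shortfall in pounds."""
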