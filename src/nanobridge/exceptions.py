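"""Exception hierarchy shared across the package."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition."""


class ZeroCapacityError(InvalidInputError):
    """A diameter too small to pack even one filament of the requested class."""


class ConfigurationError(InvalidInputError):
    """A gate / pipeline configuration is incomplete or inconsistent."""


class UndefinedResultError(InvalidInputError):
    """A quantity is undefined for the given input (e.g. empty gated set)."""


class DegenerateVarianceError(InvalidInputError):
    """All groups have zero within-group variance; the test statistic is undefined."""
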