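"""Exception hierarchy shared across the package."""


class FretPathsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FretPathsError, ValueError):
    """A parameter violates its documented domain (negative rate, bad fraction...)."""


class EstimationError(FretPathsError, RuntimeError):
    """A statistical estimate cannot be formed from the data provided."""


class DataError(FretPathsError, ValueError):
    """Input data violate a structural contract (shapes, ordering, formats)."""


class UndefinedMetricError(FretPathsError, ValueError):
    """A per-burst metric is undefined (e.g. no donor-excitation photons)."""


class PathDegeneracyError(FretPathsError, ValueError):
    """A planted network admits ties for the optimal path."""


class ConfigError(FretPathsError, ValueError):
    """Pipeline configuration is malformed (unknown keys, missing paths)."""
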