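"""Exception hierarchy shared across the package."""


class LickometryError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LickometryError, ValueError):
    """A numeric parameter violates its documented domain."""


class ConfigurationError(LickometryError, ValueError):
    """A detector/transport configuration is inconsistent or incomplete."""


class UndefinedMetricError(LickometryError, ZeroDivisionError):
    """A ratio metric was requested with an empty denominator.

    Distinct from returning 0: precision with no detections, or a
    correlation on a constant vector, has no defined value.
    """


class FormatError(LickometryError, ValueError):
    """A file does not conform to the expected dialect."""


class DataError(LickometryError, ValueError):
    """File contents parse but violate a data invariant (e.g. time order)."""
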