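"""Exception hierarchy.

All package errors derive from :class:`FdaPowerError` so callers can catch
one base class; the subclasses distinguish bad files, bad parameters and
degenerate data (the latter signals an upstream simulation bug rather than a
user mistake and is never silently regularised).
"""


class FdaPowerError(Exception):
    """Base class for all errors raised by fdapower."""


class FormatError(FdaPowerError):
    """A delimited-text file does not match the expected layout."""


class GridError(FdaPowerError):
    """Grid positions are not strictly increasing or are otherwise invalid."""


class DomainError(FdaPowerError):
    """A requested position or grid lies outside the available domain span."""


class ParameterError(FdaPowerError):
    """A numeric parameter is outside its valid range."""


class DegenerateDataError(FdaPowerError):
    """Data admit no test statistic (e.g. zero pooled variance at a point)."""


class ConfigError(FdaPowerError):
    """A sweep manifest or CLI configuration is invalid."""
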