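"""Exception hierarchy shared across the package.

All errors raised by larvarc derive from :class:`LarvarcError` so callers can
catch package failures with a single except clause.  The subclasses separate
malformed files (:class:`FormatError`), internally inconsistent data
(:class:`IntegrityError`), invalid parameters (:class:`ParameterError`),
inconsistent analysis configuration (:class:`ConfigurationError`) and data
that are valid but unusable for the requested computation
(:class:`DataError` / :class:`InsufficientDataError`).
"""


class LarvarcError(Exception):
    """Base class for all larvarc errors."""


class FormatError(LarvarcError):
    """A file or table does not conform to the expected schema."""


class IntegrityError(LarvarcError):
    """Data are schema-valid but internally inconsistent (gaps, duplicates,
    length mismatches between tables that must share one frame clock)."""


class ParameterError(LarvarcError, ValueError):
    """A parameter value is outside its admissible range."""


class ConfigurationError(LarvarcError):
    """Analysis configuration incompatible with the supplied data."""


class DataError(LarvarcError):
    """Data values make the requested computation impossible (e.g. a
    non-positive baseline fluorescence)."""


class InsufficientDataError(DataError):
    """Too few usable observations for the requested computation."""
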