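"""Exception taxonomy for the pipeline.

All pipeline errors derive from :class:`OculoConcordError` so callers can
catch the package's failures with one except clause while still
distinguishing malformed files, inconsistent data, bad arguments and
statistically undefined results.
"""


class OculoConcordError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(OculoConcordError):
    """A file violates the expected on-disk format (duplicate ids, bad header)."""


class ParseError(FormatError):
    """A cell could not be parsed; message carries row/column coordinates."""


class DataError(OculoConcordError):
    """Inputs are individually valid but mutually inconsistent
    (e.g. a probe present in the matrix but missing from the annotation)."""


class ArgumentError(OculoConcordError, ValueError):
    """An argument or configuration value is out of its admissible range."""


class UndefinedResultError(OculoConcordError):
    """The requested statistic is undefined for the given input
    (e.g. a correlation of a zero-variance vector)."""


class ConfigError(ArgumentError):
    """A pipeline configuration file failed schema validation."""
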