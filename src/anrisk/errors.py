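"""Exception hierarchy.

All package-specific failures derive from :class:`AnriskError` so callers can
catch one base class; subclasses map to the distinct failure modes of the
pipeline (file format, schema, estimation, fold construction, ...).
"""


class AnriskError(Exception):
    """Base class for all anrisk errors."""


class FormatError(AnriskError):
    """A delimited input file does not have the required layout."""


class ParseError(FormatError):
    """A cell could not be parsed; the message names row and column."""


class IntegrityError(AnriskError):
    """A table violates an identity constraint (e.g. duplicate scan_id)."""


class SchemaError(AnriskError):
    """Feature schema of a table does not match a fitted model."""


class ConfigError(AnriskError):
    """An invalid generator or pipeline configuration."""


class EstimationError(AnriskError):
    """Model estimation is impossible (e.g. too few reference-group rows)."""


class FoldError(AnriskError):
    """Cross-validation folds cannot be built from the given rows."""


class UndefinedMetricError(AnriskError):
    """A performance metric is undefined for the given labels."""


class AlignmentError(AnriskError):
    """Region labels of two inputs cannot be aligned; lists the unmatched."""
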