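"""Exception hierarchy for clonogem.

All errors raised by the package derive from :class:`ClonogemError` so callers
can catch pipeline failures with a single except clause while still
distinguishing configuration problems from malformed inputs.
"""


class ClonogemError(Exception):
    """Base class for all clonogem errors."""


class FormatError(ClonogemError):
    """A required input file is missing or structurally unusable."""


class ParseError(ClonogemError):
    """A file exists but its contents cannot be parsed."""


class SchemaError(ClonogemError):
    """A table is missing required columns."""


class LabelingError(ClonogemError):
    """A barcode cannot be mapped to a sample/condition."""


class ConfigError(ClonogemError):
    """An invalid or contradictory configuration value."""


class AllCellsFilteredError(ClonogemError):
    """QC removed every cell; raised instead of returning an empty matrix."""


class NumericalError(ClonogemError):
    """A numerical failure (NaN log-probability, singular input)."""
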