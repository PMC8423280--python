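"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`MetricFuseError`
so callers (and the CLI) can catch one base class.
"""


class MetricFuseError(Exception):
    """Base class for all metricfuse errors."""


class SchemaError(MetricFuseError):
    """A file is missing a required column or has a malformed header."""


class ParseError(MetricFuseError):
    """A cell that should be numeric could not be parsed."""


class ValidationError(MetricFuseError):
    """A domain invariant is violated (probability range, row sums, names...)."""


class AlignmentError(MetricFuseError):
    """Two aligned containers disagree on sample identity or length."""


class StratificationError(MetricFuseError):
    """A class is too small for the requested number of folds."""


class UndefinedAUCError(MetricFuseError):
    """AUC requested on labels containing a single class."""


class DegenerateWeightsError(MetricFuseError):
    """All fusion weights are zero: no convex combination exists."""


class FusionSpecError(MetricFuseError):
    """Unknown fusion method tag or inconsistent fusion specification."""


class ConfigError(MetricFuseError):
    """A run configuration references missing paths or invalid values."""
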