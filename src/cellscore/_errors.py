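"""Exception hierarchy shared across the package.

Input problems (shape, parsing, configuration) raise subclasses of
:class:`InputValidationError`; a metric that is mathematically undefined on
otherwise well-formed input raises :class:`UndefinedMetricError` so callers
(e.g. the bootstrap loop) can tell the two situations apart.
"""


class CellscoreError(Exception):
    """Base class for all package errors."""


class InputValidationError(CellscoreError, ValueError):
    """Malformed input: shapes, files, or configuration."""


class LengthMismatchError(InputValidationError):
    """Paired vectors have different lengths."""


class TooFewItemsError(InputValidationError):
    """Fewer than two scored items; no pairs exist."""


class NonFiniteError(InputValidationError):
    """A score is NaN or infinite."""


class SubmissionFormatError(InputValidationError):
    """A submission file failed validation and cannot be scored."""


class ConfigError(InputValidationError):
    """Invalid simulation configuration or algorithm profile."""


class UndefinedMetricError(CellscoreError, ArithmeticError):
    """The metric is undefined on this input (e.g. a constant reference)."""
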