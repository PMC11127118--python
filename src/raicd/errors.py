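"""Exception hierarchy for raicd.

All package-specific failures derive from :class:`RaicdError` so callers can
catch one base class at pipeline boundaries (the CLI does exactly that).
"""


class RaicdError(Exception):
    """Base class for all raicd errors."""


class InvalidCodeError(RaicdError, ValueError):
    """An ICD-10-CM code string is empty or does not conform after normalization."""


class CodeMapError(RaicdError, ValueError):
    """A parameter code map violates a structural invariant."""


class WeightTableError(RaicdError, ValueError):
    """A weight table is malformed or fails validation where validity is required."""


class EmptyCohortError(RaicdError, ValueError):
    """Inclusion filters removed every record."""


class SeparationError(RaicdError, RuntimeError):
    """The mortality model could not be fitted because a covariate separates the outcome."""


class CalibrationError(RaicdError, RuntimeError):
    """A calibration rule (threshold search, intercept solve, ...) is unsatisfiable."""


class ConfigError(RaicdError, ValueError):
    """Invalid run or simulation configuration."""
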