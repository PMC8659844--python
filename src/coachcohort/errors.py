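"""Exception hierarchy.

``DataError`` marks problems with the input tables (missing columns, unknown
labels, out-of-window days); ``ConfigError`` marks invalid configuration
(weights, thresholds, window sizes).  The CLI maps them to exit codes 1 and 2.
"""


class CoachCohortError(ValueError):
    """Base class for all package-raised errors."""


class DataError(CoachCohortError):
    """Raised when an input table or record violates the documented schema."""


class ConfigError(CoachCohortError):
    """Raised when a configuration value is invalid."""
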