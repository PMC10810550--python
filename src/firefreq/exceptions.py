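"""Exception hierarchy shared across the pipeline stages.

Exit-code mapping used by the CLI: configuration problems (2), data-format
problems (3), fit/convergence problems (4), study-level failures (5).
"""


class FirefreqError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(FirefreqError):
    """Invalid specification, bounds, or scenario configuration."""

    exit_code = 2


class DataFormatError(FirefreqError):
    """Malformed or schema-incompatible input data."""

    exit_code = 3


class GenerationError(FirefreqError):
    """Numerical failure while simulating data (e.g. exp overflow)."""

    exit_code = 2


class FitError(FirefreqError):
    """Model fitting failed outright (degenerate design, separation)."""

    exit_code = 4


class DiagnosticsError(FirefreqError):
    """MCMC run failed its convergence diagnostics."""

    exit_code = 4


class MetricError(FirefreqError):
    """A forecast metric is undefined for the given inputs."""

    exit_code = 3


class StudyError(FirefreqError):
    """Simulation-study level failure (too many excluded replicates)."""

    exit_code = 5
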