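"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/config errors -> 2, data-format
errors -> 3, numeric/degenerate errors -> 4.
"""


class ABCompareError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(ABCompareError):
    """Invalid configuration, missing files, inconsistent design."""

    exit_code = 2


class FormatError(ABCompareError):
    """Malformed or inconsistent on-disk data."""

    exit_code = 3


class NumericError(ABCompareError):
    """Degenerate or numerically unusable inputs."""

    exit_code = 4


class DegenerateChromosomeError(NumericError):
    """A chromosome has too few usable bins to analyse."""


class CannotOrientError(NumericError):
    """Covariates carry no signal, so the compartment sign is undefined."""
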