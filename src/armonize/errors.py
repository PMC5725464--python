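"""Exception hierarchy shared across the package.

Exit codes mirror the CLI contract: 2 for configuration problems, 3 for
malformed or inconsistent data, 4 for numerical degeneracies.
"""


class ArmonizeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(ArmonizeError):
    """Invalid configuration: bad parameter values, missing columns, bad paths."""

    exit_code = 2


class DataError(ArmonizeError):
    """Malformed or internally inconsistent input data."""

    exit_code = 3


class NumericalError(ArmonizeError):
    """Numerical degeneracy: rank deficiency, zero variance, too few values."""

    exit_code = 4


class FitError(NumericalError):
    """A regression could not be fitted (too few usable observations)."""


class RankDeficiencyError(NumericalError):
    """Regressors are collinear to machine precision."""

    def __init__(self, message, dependent_columns=()):
        super().__init__(message)
        self.dependent_columns = tuple(dependent_columns)


class SelectionError(NumericalError):
    """Too few finite values to compute boxplot fences."""
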