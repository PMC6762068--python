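"""Exception hierarchy.

Exit-code mapping used by the CLI:
  2 -- bad input data (InputError, ValidationError)
  3 -- bad configuration or hyperparameters (ConfigurationError, ParameterError)
  4 -- convergence failures (FitError, TrainingError)
  5 -- file / model I/O problems (ModelIOError)
"""


class ValveMonitorError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(ValveMonitorError):
    """Invalid input data (shape, dimension, emptiness)."""

    exit_code = 2


class ValidationError(ValveMonitorError):
    """A file or recording failed validation (non-uniform sampling, bad rows)."""

    exit_code = 2


class ConfigurationError(ValveMonitorError):
    """A configuration field is out of its valid range."""

    exit_code = 3


class ParameterError(ValveMonitorError):
    """Infeasible hyperparameters or an empty search grid."""

    exit_code = 3


class FitError(ValveMonitorError):
    """Sinusoid fit failed to converge or the input is degenerate.

    Carries the last iterate in ``last_params`` when available.
    """

    exit_code = 4

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class TrainingError(ValveMonitorError):
    """SVM training failed to converge within the iteration budget."""

    exit_code = 4

    def __init__(self, message, n_iterations=None):
        super().__init__(message)
        self.n_iterations = n_iterations


class StandardizationError(ValveMonitorError):
    """A feature axis has zero variance and cannot be standardized."""

    exit_code = 2


class ModelIOError(ValveMonitorError):
    """Model file missing, corrupt, or schema-incompatible."""

    exit_code = 5
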