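"""Exception hierarchy for adefield."""


class AdefieldError(Exception):
    """Base class for all package errors."""


class GridError(AdefieldError, ValueError):
    """Invalid grid construction parameters."""


class StabilityError(AdefieldError, RuntimeError):
    """The implicit operator symbol is non-positive at some mode.

    Signals a time step too large (or inconsistent parameters) for the
    semi-implicit solve.
    """


class BlowUpError(AdefieldError, RuntimeError):
    """The phase field left its physical range or became non-finite."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step


class SolverError(AdefieldError, RuntimeError):
    """An iterative solver failed to converge."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class InvalidTargetsError(AdefieldError, ValueError):
    """Constraint targets are degenerate (e.g. non-positive reference area)."""


class ConfigError(AdefieldError, ValueError):
    """Malformed run configuration or unknown preset."""
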