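"""Exception types shared across the pipeline."""


class TrimeditError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrimeditError, ValueError):
    """Invalid simulation or filter configuration; message names the field."""


class InputError(TrimeditError, ValueError):
    """Malformed input table (duplicates, unknown strand, missing columns)."""


class DesignError(TrimeditError, ValueError):
    """Degenerate or collinear model design."""


class ConvergenceError(TrimeditError, RuntimeError):
    """GLM failed to converge or separated; carries the last deviance."""

    def __init__(self, message: str, deviance: float | None = None):
        super().__init__(message)
        self.deviance = deviance
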