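"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A parameter combination or input layout that cannot be processed."""


class SchemaError(ValueError):
    """A container or table whose schema does not match the expected layout."""


class NoDetectionError(RuntimeError):
    """No wave arrival could be detected in a trace.

    Carries diagnostics useful for debugging acquisition problems.
    """

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics


class InvalidMeasurementError(ValueError):
    """A time-of-flight measurement inconsistent with the calibration."""


class FitFailureError(RuntimeError):
    """Nonlinear model fit failed to converge from every starting point."""
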