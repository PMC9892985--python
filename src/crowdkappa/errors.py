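"""Exception hierarchy shared across the package."""


class CrowdKappaError(Exception):
    """Base class for all package errors."""


class ValidationError(CrowdKappaError):
    """Input data or domain-object invariant violated."""


class ConfigError(CrowdKappaError):
    """Configuration value outside its admissible range."""


class CalibrationError(CrowdKappaError):
    """Difficulty calibration failed to converge.

    Carries the bisection trace so the failure can be inspected.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []
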