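"""Exception types used across the package."""


class AmpcytError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(AmpcytError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(AmpcytError, ValueError):
    """Input is formally valid but makes the requested quantity undefined."""


class CalibrationError(AmpcytError, RuntimeError):
    """Bead-based calibration could not be performed."""
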