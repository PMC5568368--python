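"""Exception hierarchy shared across the package."""


class MipoolError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgument(MipoolError, ValueError):
    """An input violates a documented precondition."""


class FitFailure(MipoolError, RuntimeError):
    """A model fit did not converge (non-convergence or separation)."""


class SingularMatrixError(MipoolError, RuntimeError):
    """A matrix that must be inverted is (numerically) singular."""


class CalibrationError(MipoolError, RuntimeError):
    """Numerical calibration of a missingness intercept failed."""


class DataError(MipoolError, ValueError):
    """A dataset or stack file is malformed."""
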