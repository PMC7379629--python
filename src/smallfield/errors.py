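"""Exception hierarchy shared by all pipeline stages."""


class SmallFieldError(Exception):
    """Base class for all package errors."""


class DegenerateFieldError(SmallFieldError):
    """A dose profile has no half-maximum crossing (flat or monotone field)."""


class BoundsError(SmallFieldError):
    """A region of interest or fit window extends beyond the dose map."""


class FitError(SmallFieldError):
    """A nonlinear fit failed to converge from every starting point."""


class CoverageError(SmallFieldError):
    """Input data do not span the field sizes a fit or pipeline stage needs."""


class CalibrationError(SmallFieldError):
    """An ill-conditioned or missing detector calibration."""


class AlignmentError(SmallFieldError):
    """Two series that must cover the same fields do not."""


class ConfigError(SmallFieldError):
    """Invalid configuration or simulation request."""
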