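"""Exception hierarchy for assay-analysis failure modes.

Estimation failures are signals a caller is expected to branch on (for
example falling back to the Hill-MCMC estimator when interpolation finds
no bracketing pair), so each mode gets its own class.
"""


class NabstatError(Exception):
    """Base class for all package-specific errors."""


class CurveError(NabstatError):
    """Invalid neutralization-curve data."""


class BelowRangeError(NabstatError):
    """Every tested dilution left transduction above 50%.

    The ND50 lies beyond the weakest tested inhibition; the threshold
    method cannot return an estimate.
    """


class BracketNotFoundError(NabstatError):
    """No adjacent dilution pair brackets the 50% transduction level.

    Raised by the linear-bootstrap estimator; callers typically fall back
    to the Hill-MCMC estimator, which can extrapolate.
    """


class AsymptoteAboveHalfError(NabstatError):
    """Hill curve with bottom >= 0.5 never crosses 50% transduction."""


class ConvergenceError(NabstatError):
    """MCMC diagnostics are missing or the sampler failed outright."""


class PlateError(NabstatError):
    """Malformed plate export, layout metadata, or control wells."""


class NoSignalError(PlateError):
    """Antibody-free control signal does not exceed background."""
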