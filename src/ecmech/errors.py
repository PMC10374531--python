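"""Exception hierarchy.

Every failure mode that callers are expected to handle has its own class;
all inherit from :class:`ECMechError` so pipeline code can catch per-curve
problems without masking programming errors.
"""


class ECMechError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ECMechError, ValueError):
    """Invalid parameter values (weights not summing to one, negative radius...)."""


class GenerationError(ECMechError):
    """The synthetic forward model could not produce a physical curve."""


class FormatError(ECMechError):
    """A dataset on disk violates the container schema.

    The message names the offending file and field.
    """


class CurveValidationError(ECMechError):
    """A stored curve violates the raw-curve invariants; names the curve id."""


class CalibrationError(ECMechError):
    """Deflection-sensitivity estimation failed (e.g. non-positive contact slope)."""


class ContactNotFoundError(ECMechError):
    """No candidate contact point with positive post-contact slope exists."""


class EmptyContactError(ECMechError):
    """Rescaling produced no positive-indentation points; curve unusable."""


class FitError(ECMechError):
    """Hertz fit failed: too few points in the window or non-physical prefactor."""


class InsufficientDataError(ECMechError):
    """Too few values for a distribution-level estimate (per-FV median)."""


class AllCurvesFailedError(ECMechError):
    """Every cell of a force volume failed contact detection, rescaling or fitting."""
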