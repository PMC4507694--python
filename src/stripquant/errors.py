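"""Exception hierarchy for the strip-assay pipeline.

All errors derive from :class:`StripQuantError`; callers that only need
"did the pipeline fail" can catch the base class, while tests and the CLI
discriminate on subclasses.
"""


class StripQuantError(Exception):
    """Base class for all package errors."""


class InputError(StripQuantError):
    """Invalid argument values, missing files, malformed configuration."""


class FormatError(InputError):
    """A file exists but cannot be decoded in an expected format."""


class GeometryError(StripQuantError):
    """A spot region (or its sampling locus) falls outside the image."""


class DetectionError(StripQuantError):
    """Automatic spot detection found nothing usable."""


class InsufficientReplicatesError(InputError):
    """A statistic that needs >= 2 replicate values received fewer."""


class FitError(StripQuantError):
    """Curve fitting failed to converge or the data are degenerate.

    Carries the initialization used so the failure is reproducible.
    """

    def __init__(self, message: str, p0=None, residuals=None):
        super().__init__(message)
        self.p0 = p0
        self.residuals = residuals


class CalibrationRangeError(StripQuantError):
    """A signal lies outside the invertible range of a calibration curve."""


class LODUndefinedError(StripQuantError):
    """The blank-plus-noise signal exceeds the curve saturation; the assay
    cannot detect at all under these conditions."""
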