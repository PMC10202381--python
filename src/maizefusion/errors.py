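"""Exception hierarchy for the fusion pipeline.

Every stage raises a subclass of :class:`MaizeFusionError`, so callers can
distinguish pipeline failures from programming errors.
"""


class MaizeFusionError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(MaizeFusionError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(MaizeFusionError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class InsufficientFeaturesError(MaizeFusionError):
    """Too few keypoints to attempt an alignment."""


class RegistrationFailureError(MaizeFusionError):
    """Robust consensus could not find enough inliers."""


class InsufficientCorrespondencesError(MaizeFusionError):
    """Fewer matched point pairs than the calibration gate requires."""

    def __init__(self, needed: int, given: int):
        self.needed = needed
        self.given = given
        super().__init__(
            f"DLT estimation needs at least {needed} correspondences, got {given}"
        )


class DegenerateGeometryError(MaizeFusionError):
    """Correspondence geometry leaves the linear system rank deficient."""


class RegistrationQualityError(MaizeFusionError):
    """Fitted model's reprojection error exceeds the configured threshold."""


class ConfigError(MaizeFusionError):
    """Pipeline configuration is invalid; reported before any compute."""
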