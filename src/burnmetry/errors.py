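"""Exception hierarchy for burnmetry."""


class BurnmetryError(Exception):
    """Base class for all burnmetry errors."""


class InvalidDepthError(BurnmetryError):
    """Depth sample is non-positive or non-finite."""


class InvalidExtrinsicsError(BurnmetryError):
    """Rotation matrix is not a proper orthonormal rotation."""


class DimensionMismatchError(BurnmetryError):
    """Depth map, mask or grid shapes disagree."""


class DegenerateContourError(BurnmetryError):
    """Contour has fewer than 3 points, or all points are collinear."""


class NoWoundError(BurnmetryError):
    """Mask contains no measurable wound component."""


class UnmeasurableWoundError(BurnmetryError):
    """Wound region yields no valid surface triangle."""


class OutOfModelError(BurnmetryError):
    """Requested template wraps beyond the validity domain of the surface model."""


class FieldOfViewError(BurnmetryError):
    """Template region is clipped by the image border or occluded by the surface."""


class DepthFormatError(BurnmetryError):
    """Depth file is malformed (bad magic, truncated or inconsistent header)."""


class DegenerateFitError(BurnmetryError):
    """Regression input has constant abscissa or too few records."""
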