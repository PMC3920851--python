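"""Exception hierarchy for ctwear.

Errors are split by failure mode so that callers (and the CLI) can
distinguish bad geometry from bad inputs from algorithmic failure.
"""


class CtwearError(Exception):
    """Base class for all ctwear-specific errors."""


class DegenerateGeometryError(CtwearError, ValueError):
    """Colinear / coplanar / coincident input where a nondegenerate
    configuration is required (plane fit, circumsphere, sphere fit)."""


class ConfigurationError(CtwearError, ValueError):
    """A parameter set that is internally inconsistent, e.g. an implant
    that does not fit inside the voxel grid."""


class EmptySurfaceError(CtwearError, RuntimeError):
    """Surface extraction found no candidate points — usually a wrong
    threshold or misplaced landmarks."""


class InsufficientPointsError(CtwearError, ValueError):
    """Too few (or too tightly clustered) surface points to sample
    admissible four-point subsets."""


class FittingError(CtwearError, RuntimeError):
    """Robust sphere fitting could not produce an estimate (all samples
    degenerate, or every point pruned)."""


class VolumeFormatError(CtwearError, ValueError):
    """A volume file lacks required spatial metadata (e.g. voxel spacing)
    or cannot be interpreted as a 3-D scalar image."""


class LandmarkValidationError(CtwearError, ValueError):
    """A landmark table does not encode the seven-landmark protocol."""
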