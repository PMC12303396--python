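"""Exception hierarchy for the capmorph pipeline.

Every stage raises a subclass of :class:`CapmorphError`, so callers (and the
CLI) can distinguish configuration problems from geometric/algorithmic
failures without string matching.
"""


class CapmorphError(Exception):
    """Base class for all capmorph errors."""


class ConfigError(CapmorphError):
    """Invalid run configuration (missing paths, bad parameter values)."""


# ---------------------------------------------------------------------------
# mesh_io
# ---------------------------------------------------------------------------

class MeshFormatError(CapmorphError):
    """A mesh file could not be parsed in the requested format."""


class MissingColorError(MeshFormatError):
    """The mesh file carries no per-vertex color."""


class MaskError(CapmorphError):
    """A binary volume is unusable for surface extraction."""


class EmptyMaskError(MaskError):
    """The binary mask contains no foreground voxels."""


class FullMaskError(MaskError):
    """The binary mask has no background boundary inside the volume."""


class LandmarkError(CapmorphError):
    """Landmark set violates its invariants or cannot be read."""


# ---------------------------------------------------------------------------
# fiducial detection
# ---------------------------------------------------------------------------

class ClusteringError(CapmorphError):
    """Fiducial clustering failed."""


class TooFewPointsError(ClusteringError):
    """Fewer filtered points than requested clusters."""


class InfeasibleClusteringError(ClusteringError):
    """No k-partition satisfying the diameter bound within the restart budget."""


# ---------------------------------------------------------------------------
# module pose
# ---------------------------------------------------------------------------

class PoseError(CapmorphError):
    """Module pose recovery failed for one cluster."""


class DegenerateClusterError(PoseError):
    """Cluster points are collinear or coincident; no plane can be fit."""


class TooFewClustersError(PoseError):
    """Not enough cluster centroids to estimate the head center."""


class AmbiguousNormalError(PoseError):
    """Inward-normal sign cannot be decided (plane through the head center)."""


class LegAmbiguityError(PoseError):
    """Observed triangle legs are too close in length to orient the module."""


class PoseFitError(PoseError):
    """Residual between posed model and observed triangle exceeds the bound."""


class MinModulesError(CapmorphError):
    """Fewer modules were posed successfully than the configured minimum."""


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

class MontageError(CapmorphError):
    """10-20 / 10-5 montage construction failed."""


class NoIntersectionError(MontageError):
    """The slicing plane misses the mesh between the two endpoints."""


class OpenSurfaceError(MontageError):
    """The plane-slice curve is interrupted (open or fragmented surface)."""


class CzConvergenceError(MontageError):
    """The vertex (Cz) iteration did not converge."""


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

class RegistrationError(CapmorphError):
    """Point-set or surface registration failed."""


class TooFewCorrespondencesError(RegistrationError):
    """Fewer than three shared labels between the two point sets."""


class DegenerateConfigurationError(RegistrationError):
    """Correspondence points are collinear; rotation is under-determined."""


class CoplanarSourceError(RegistrationError):
    """Four-point affine source points are coplanar (singular system)."""

    def __init__(self, message: str, tetra_volume: float = 0.0):
        super().__init__(message)
        self.tetra_volume = tetra_volume


class InsufficientSampleError(RegistrationError):
    """Too few sparse-sample points to constrain the template fit."""


class FitConvergenceError(RegistrationError):
    """Scaled-ICP template fit did not converge within max iterations."""


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class MetricsError(CapmorphError):
    """Error-report computation failed."""


class LabelMismatchError(MetricsError):
    """Two montages do not share an identical label set."""

    def __init__(self, message: str, missing=(), extra=()):
        super().__init__(message)
        self.missing = tuple(missing)
        self.extra = tuple(extra)


class EmptyInputError(MetricsError):
    """An empty error map or report list was supplied."""


class MixedMethodError(MetricsError):
    """Reports from different methods were mixed in one grand mean."""


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

class PhantomError(CapmorphError):
    """Synthetic phantom generation failed."""


class ResolutionError(PhantomError):
    """Requested mesh resolution is too coarse for the head size."""


class ModuleOverlapError(PhantomError):
    """Two placed modules intersect."""
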