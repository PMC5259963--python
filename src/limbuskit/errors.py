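"""Exception and warning types shared across the package."""


class LimbuskitError(Exception):
    """Base class for all package-specific errors."""


class InvalidROIError(LimbuskitError):
    """Region of interest falls outside the image stack."""


class DegenerateImageError(LimbuskitError):
    """Image has too little contrast for thresholding (e.g. constant)."""


class InfeasibleGeometryError(LimbuskitError):
    """Scene configuration cannot realize its targets (ROI too small, etc.)."""


class NoLumenFoundError(LimbuskitError):
    """No below-threshold component of sufficient area inside the ROI."""


class InvalidRangeError(LimbuskitError):
    """Empty or out-of-bounds depth range."""


class EmptySegmentationError(LimbuskitError):
    """Threshold segmentation produced an empty tissue mask."""


class InvalidSeedError(LimbuskitError):
    """Region-growing seed voxel lies outside the tissue mask."""


class MeshError(LimbuskitError):
    """Mesh is non-conforming, empty or degenerate."""


class BoundaryLabelingError(LimbuskitError):
    """No pressure faces or no fixed faces could be labeled."""


class DegenerateElementError(LimbuskitError):
    """Tetrahedron with non-positive volume."""


class IncompressibleLimitError(LimbuskitError):
    """Poisson ratio at (or beyond) the incompressible limit 0.5."""


class UnloadedModelError(LimbuskitError):
    """No pressure faces are labeled; the model carries no load."""


class InsufficientConstraintError(LimbuskitError):
    """Fixed set empty or reduced stiffness singular (rigid modes remain)."""


class SolverError(LimbuskitError):
    """Linear solver failed to reach the required residual."""


class NonConvexLumenWarning(UserWarning):
    """Lumen centroid falls outside the mask; chords are measured anyway."""
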