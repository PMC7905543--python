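"""Exception hierarchy shared across the package."""


class FragDispError(Exception):
    """Base class for all fragdisp errors."""


class MeshFormatError(FragDispError):
    """A mesh file could not be parsed in a supported format."""


class EmptyMeshError(MeshFormatError):
    """A mesh file parsed but contains no faces."""


class InvalidPoseError(FragDispError):
    """A pose matrix is not a proper rigid motion (reflection, shear, scale)."""


class TableValidationError(FragDispError):
    """A plan or rater table violates its schema or consistency rules."""


class DegenerateGeometryError(FragDispError):
    """A point set does not span enough dimensions for the requested operation."""


class RegistrationAmbiguityError(FragDispError):
    """Point correspondences do not determine a unique rotation (collinear set)."""


class NonRigidInputError(FragDispError):
    """Two vertex sets are not related by a rigid motion within tolerance."""


class DegenerateVarianceError(FragDispError):
    """Every group has zero within-group variance; the F statistic is undefined."""


class UndefinedStatisticError(FragDispError):
    """Too few observations, or zero predictor variance, for the statistic."""
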