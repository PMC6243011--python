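"""Exception hierarchy shared across the toolkit."""


class VoxelproofError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(VoxelproofError, ValueError):
    """Malformed input value (bad status string, infeasible spec, bad regex, ...)."""


class DimensionalityError(VoxelproofError, ValueError):
    """Array input is not 3D or shapes are incongruent."""


class BodyNotFoundError(VoxelproofError, KeyError):
    """Requested body ID has no foreground voxels in the addressed version."""


class VersionNotFoundError(VoxelproofError, KeyError):
    """Requested version ID is not a committed version of the store."""


class ImmutabilityError(VoxelproofError):
    """Attempted mutation of a committed (frozen) version."""


class ConsistencyError(VoxelproofError):
    """A split partition references voxels outside the body, or regions overlap."""


class ConfigurationError(VoxelproofError):
    """The store is missing a required companion (e.g. grayscale volume)."""


class LockError(VoxelproofError):
    """A mutation was attempted without holding the required body lock."""


class OwnershipError(LockError):
    """Release attempted by a user who does not hold the lock."""


class InsufficientSeedsError(VoxelproofError):
    """Fewer than two distinct seed labels survive inside the foreground."""


class SeedOutsideBoxError(VoxelproofError):
    """A surviving seed lies outside the user-supplied bounding box."""
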