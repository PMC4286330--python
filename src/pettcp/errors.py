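"""Exception hierarchy."""


class PETTCPError(Exception):
    """Base class for all package errors."""


class ConfigError(PETTCPError, ValueError):
    """Invalid configuration (generator, grid or pipeline)."""


class GeometryError(PETTCPError, ValueError):
    """A synthetic tumor cannot be placed in the requested grid."""


class GridMismatchError(PETTCPError, ValueError):
    """Paired volumes do not share a voxel grid; registration is assumed upstream."""


class EmptyMaskError(PETTCPError, ValueError):
    """No voxel exceeds the delineation threshold."""


class LabelError(PETTCPError, ValueError):
    """Unknown pathologic-response label."""
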