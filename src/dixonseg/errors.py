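"""Exception hierarchy shared across the pipeline stages."""


class DixonSegError(Exception):
    """Base class for all package errors."""


class GeometryError(DixonSegError):
    """Phantom geometry does not fit the requested grid."""


class AlignmentError(DixonSegError):
    """Volumes that must share a grid/affine do not."""


class SlabError(DixonSegError):
    """Slab selection out of bounds or empty."""


class PatchingError(DixonSegError):
    """Invalid patch extraction, filtering, split or reconstruction."""


class ArchitectureError(DixonSegError):
    """Network configuration incompatible with the input geometry."""


class TrainingError(DixonSegError):
    """Training invoked on an unusable patch set."""


class DesignError(DixonSegError):
    """Statistical design invalid (unbalanced table, missing cell, ...)."""


class StatsError(DixonSegError):
    """Degenerate or out-of-domain statistical input."""
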