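"""Exception hierarchy shared across the package."""


class ScalpmapError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(ScalpmapError, ValueError):
    """A mesh file or mesh object violates the format contract."""


class DegenerateGeometryError(ScalpmapError, ValueError):
    """Input geometry is rank-deficient (collinear/coplanar landmarks, ...)."""


class EmptyResultError(ScalpmapError, ValueError):
    """An operation produced an empty geometry or region."""


class ConvergenceError(ScalpmapError, RuntimeError):
    """An iterative procedure failed to reach its target.

    Carries ``best`` — the best value achieved — where meaningful.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class LayoutDensityError(ScalpmapError, ValueError):
    """Requested marker layout is too dense for the marker size or mesh."""


class StageError(ScalpmapError, RuntimeError):
    """A pipeline stage failed; names the stage and offending input."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
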