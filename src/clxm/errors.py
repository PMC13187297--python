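"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A user-supplied parameter is infeasible or out of range."""


class GeometryError(ValueError):
    """A requested geometry (slab, window, field of view) does not fit."""


class TrackingError(RuntimeError):
    """The fiducial marker could not be followed through every frame."""

    def __init__(self, frame: int, message: str = ""):
        self.frame = frame
        super().__init__(message or f"marker lost at frame {frame}")


class StageOrderError(RuntimeError):
    """A processing stage was applied in an order its physics forbids."""


class DependencyError(RuntimeError):
    """A pipeline stage is missing the outputs of an earlier stage."""
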