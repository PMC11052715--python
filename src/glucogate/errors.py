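"""Exception types shared across the package."""


class GlucogateError(Exception):
    """Base class for package-specific errors."""


class ResolutionError(GlucogateError):
    """Sampling interval too coarse for the requested depth resolution."""


class GateOverlapError(GlucogateError):
    """A time/depth gate does not overlap the signal support."""


class FitError(GlucogateError):
    """A required curve fit did not converge."""


class GridDomainError(GlucogateError):
    """A (reference, predicted) pair lies outside the error-grid domain."""


class DatasetFormatError(GlucogateError):
    """An on-disk dataset is malformed, truncated or of unknown schema."""


class PipelineStageError(GlucogateError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
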