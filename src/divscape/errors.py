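"""Exception hierarchy shared across the package."""


class DivscapeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DivscapeError, ValueError):
    """A delimited input file violates the expected layout or token set."""


class DatasetBelowThresholdError(DivscapeError):
    """Dataset rejected: fewer surviving populations than the inclusion minimum."""


class InsufficientSampleError(DivscapeError):
    """No locus with enough non-missing individuals to estimate diversity."""


class EmptyBandSetError(DivscapeError):
    """Target population carries no band at any locus; rarity undefined."""


class ZeroVarianceError(DivscapeError, ValueError):
    """A statistic that requires variation was given constant values."""


class ConvergenceError(DivscapeError):
    """An iterative solver failed to converge; message names the penalty value."""


class AchievableRangeError(DivscapeError, ValueError):
    """A requested simulation effect lies outside the attainable range."""


class GridError(DivscapeError, ValueError):
    """Raster grid is malformed, non-geographic, or incompatible with the stack."""


class PipelineStageError(DivscapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
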