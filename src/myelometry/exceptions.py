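"""Exception hierarchy for the morphometry pipeline."""


class MyelometryError(Exception):
    """Base class for all package-specific errors."""


class SceneDensityError(MyelometryError):
    """Axon placement failed within the retry budget: density infeasible."""


class SegmentationError(MyelometryError):
    """Reference segmentation cannot proceed (e.g. constant image)."""


class MaskError(MyelometryError):
    """External mask is unusable (shape mismatch, non-binary values)."""


class EllipseFitError(MyelometryError):
    """Ellipse underdetermined or degenerate point set."""


class BrokenRingError(MyelometryError):
    """A measurement ray found no outer-contour crossing (broken ring)."""


class InvertedRingError(MyelometryError):
    """Outer diameter not larger than inner diameter."""


class StatsError(MyelometryError):
    """Invalid input to a statistical routine."""


class PipelineError(MyelometryError):
    """A pipeline stage failed; message names the stage."""
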