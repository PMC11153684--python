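"""Exception hierarchy for the lungmet pipeline."""


class LungmetError(Exception):
    """Base class for all lungmet-specific failures."""


class FormatError(LungmetError):
    """Malformed or unreadable input file."""


class PhantomError(LungmetError):
    """Invalid phantom specification (e.g. vessel root outside the lungs)."""


class NoTumorFoundError(LungmetError):
    """No candidate primary tumor above the adaptive intensity threshold."""


class SegmentationError(LungmetError):
    """A 2D slice could not be segmented (Hough or contour-closure failure)."""


class GraphConstructionError(LungmetError):
    """Vessel graph could not be connected within the round budget."""


class FlowError(LungmetError):
    """Flow system is singular or its input is not a connected tree."""


class PipelineError(LungmetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
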