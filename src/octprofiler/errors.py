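"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`OctProfilerError` so the
orchestrator can report which stage failed without string matching.
"""


class OctProfilerError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(OctProfilerError):
    """Device geometry is inconsistent or non-physical."""


class ConfigError(OctProfilerError):
    """A phantom or case configuration is invalid."""


class DelimitationError(OctProfilerError):
    """The scanline band or thresholding step cannot proceed."""


class LesionNotFoundError(DelimitationError):
    """No lateral column run qualifies as lesion."""


class AnnotationError(OctProfilerError):
    """Surface annotation is missing or inconsistent with the image."""


class RoiError(OctProfilerError):
    """ROI geometry is invalid (no room, bad bounds, bad depth limit)."""


class FitError(OctProfilerError):
    """A single A-scan profile cannot be fitted."""


class QualityError(OctProfilerError):
    """Too few A-scan fits converged to summarize a region."""


class TextureError(OctProfilerError):
    """GLCM geometry is invalid (box vs offset, empty section)."""


class StageError(OctProfilerError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause
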