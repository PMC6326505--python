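"""Exception hierarchy for paintbox."""


class PaintboxError(Exception):
    """Base class for all paintbox errors."""


class FormatError(PaintboxError):
    """A file could not be parsed in the requested format."""


class MetadataError(PaintboxError):
    """Volume metadata (spacing, origin, shape) is missing or invalid."""


class ConfigurationError(PaintboxError):
    """A phantom / prescription / beam configuration is inconsistent."""


class EmptySegmentationError(PaintboxError):
    """Segmentation produced no voxels (e.g. an all-zero SUV map)."""


class AssemblyError(PaintboxError):
    """The linear program could not be assembled from its inputs."""


class SolverError(PaintboxError):
    """The LP solver failed; carries a diagnostic report."""

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}
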