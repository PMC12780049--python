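"""Exception hierarchy shared across the package."""


class SpotfuseError(Exception):
    """Base class for all package-specific failures."""


class FormatError(SpotfuseError):
    """A file or table does not conform to the expected layout."""


class FilterError(SpotfuseError):
    """A quality filter removed everything, or was misconfigured."""


class TransformError(SpotfuseError):
    """Landmark configuration or transform estimation failure."""


class MappingError(SpotfuseError):
    """Pixel-to-spot assignment produced an unusable result."""


class ConfigError(SpotfuseError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(SpotfuseError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        text = f"stage '{stage}' failed: {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
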