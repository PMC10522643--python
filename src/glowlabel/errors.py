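"""Exception hierarchy shared across the package."""


class GlowlabelError(Exception):
    """Base class for all package-specific errors."""


class InvalidScheduleError(GlowlabelError):
    """A trigger schedule violates a timing constraint."""


class InputOrderError(GlowlabelError):
    """An input stream is not sorted as required."""


class InputError(GlowlabelError):
    """An input array or record is malformed."""


class ConfigError(GlowlabelError):
    """A configuration mapping fails validation."""


class ExportError(GlowlabelError):
    """A dataset export cannot be written consistently."""


class DetectorFailure(GlowlabelError):
    """Raised by a detector adapter when inference fails on a frame."""


class StageError(GlowlabelError):
    """A pipeline stage aborted; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
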