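"""Exception types shared across the package."""


class EndoquantError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EndoquantError, ValueError):
    """A generator or analyzer was configured with impossible parameters."""


class InsufficientDataError(EndoquantError, ValueError):
    """A measurement window or baseline is not covered by the recording."""


class StageError(EndoquantError, RuntimeError):
    """A pipeline stage failed; earlier stage outputs are preserved."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
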