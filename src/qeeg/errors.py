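"""Exception and warning hierarchy shared by all qeeg stages."""


class QEEGError(Exception):
    """Base class for all qeeg errors."""


class FormatError(QEEGError):
    """A file could not be parsed as the format it claims to be."""


class ValidationError(QEEGError):
    """An input violates a documented invariant."""


class MissingChannelError(ValidationError):
    """Required electrode labels are absent from a recording."""

    def __init__(self, missing, context=""):
        self.missing = tuple(sorted(missing))
        msg = f"missing required channels: {', '.join(self.missing)}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class InsufficientDataError(QEEGError):
    """Not enough clean data to satisfy the epoch-selection contract."""


class DegenerateDataError(QEEGError):
    """A statistic is undefined on this input (e.g. zero-variance differences)."""


class PipelineError(QEEGError):
    """A pipeline stage failed; message names the stage and subject."""


class DegenerateSignalWarning(UserWarning):
    """A signal is degenerate (e.g. constant) and a convention was applied."""
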