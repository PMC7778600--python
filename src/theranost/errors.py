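"""Exception hierarchy shared across the package."""


class TheranostError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TheranostError, ValueError):
    """Raised when a spectrum, collection, or configuration violates an invariant."""


class ParseError(TheranostError, ValueError):
    """Raised when a delimited-text file cannot be parsed into spectra."""


class StageError(TheranostError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name.

    The original exception is chained so the underlying cause stays visible.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
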