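"""Exception types shared across the package."""


class NumericalError(RuntimeError):
    """A filtering step failed numerically (non-finite values, non-PSD
    covariance after jitter, singular innovation covariance).

    The message names the series/time index where the failure occurred
    whenever that context is available.
    """


class FormatError(ValueError):
    """A data file could not be parsed; the message names the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        if path is not None:
            message = f"{path}: {message}"
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.path = path
        self.line = line
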