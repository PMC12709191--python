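"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: usage errors -> 1, ``DataError``
(bad input files, malformed records, out-of-range values) -> 2, any
other exception -> 3.
"""


class GcrmapError(Exception):
    """Base class for all package errors."""


class DataError(GcrmapError):
    """Invalid or malformed input data."""


class ConfigurationError(DataError):
    """Inconsistent configuration or annotation setup."""


class StageError(GcrmapError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"[stage: {stage}] {original}")
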