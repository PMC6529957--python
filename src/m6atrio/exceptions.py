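"""Exception hierarchy shared across the pipeline.

The CLI maps these onto process exit codes: InputError -> 1,
ConfigurationError -> 2, StageError -> 3.
"""


class M6aTrioError(Exception):
    """Base class for all package errors."""


class InputError(M6aTrioError):
    """A data file or value violates the documented input contract."""


class ConfigurationError(M6aTrioError):
    """A dialect, column mapping, or pipeline configuration is invalid."""


class StageError(M6aTrioError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
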