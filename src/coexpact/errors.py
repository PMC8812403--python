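"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
StageError -> 4.
"""


class CoexpactError(Exception):
    """Base class for all package errors."""


class ConfigError(CoexpactError):
    """Invalid configuration (bad thresholds, missing files, bad specs)."""


class DataError(CoexpactError):
    """Input data violates a precondition (shape, missingness, degeneracy)."""


class StageError(CoexpactError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
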