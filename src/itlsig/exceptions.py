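"""Exception hierarchy.

Validation problems (bad inputs, bad configuration) and stage failures are
kept distinct so the command-line layer can map them to exit codes 2 and 3.
"""


class ItlsigError(Exception):
    """Base class for all package errors."""


class ValidationError(ItlsigError):
    """Malformed input data or invalid parameter values."""


class ConfigurationError(ValidationError):
    """Invalid simulation or run configuration."""


class EmptyResultError(ItlsigError):
    """An operation produced an empty result where a non-empty one is required
    (e.g. quality-control filtering removed every cell)."""


class StageError(ItlsigError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
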