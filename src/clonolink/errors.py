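"""Exception hierarchy for clonolink.

All package-specific failures derive from :class:`ClonolinkError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class ClonolinkError(Exception):
    """Base class for all clonolink errors."""


class ConfigurationError(ClonolinkError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(ClonolinkError):
    """A malformed input file (missing columns, bad rows, wrong dialect)."""


class GenerationError(ClonolinkError):
    """A synthetic-data request that cannot be satisfied."""


class ConsistencyError(ClonolinkError):
    """Inputs that are individually valid but mutually inconsistent."""


class PipelineError(ClonolinkError):
    """A pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
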