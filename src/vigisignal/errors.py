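"""Exception hierarchy for vigisignal."""


class VigisignalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(VigisignalError):
    """Invalid configuration, lexicon, or term-map input."""


class FormatError(VigisignalError):
    """Malformed line listing or mapping file."""


class PipelineError(VigisignalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
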