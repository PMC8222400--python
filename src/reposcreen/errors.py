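"""Exception hierarchy shared across the package."""


class ReposcreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ReposcreenError, ValueError):
    """A parameter is outside its documented domain."""


class ConfigurationError(ReposcreenError):
    """A configuration object or mapping is internally inconsistent."""


class ParseError(ReposcreenError):
    """An input file violates its format contract."""


class GenerationError(ReposcreenError):
    """A synthetic-data generator could not satisfy its constraints."""


class ScoringError(ReposcreenError):
    """A drug could not be scored (e.g. no targets map into the network)."""


class NullDistributionError(ReposcreenError):
    """The randomization null is degenerate (zero variance)."""


class ValidationError(ReposcreenError, ValueError):
    """Input data fails a precondition check."""


class PipelineStageError(ReposcreenError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
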