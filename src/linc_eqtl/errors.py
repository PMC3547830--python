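"""Exception hierarchy shared across the package."""


class LincEqtlError(Exception):
    """Base class for all package errors."""


class ParameterError(LincEqtlError, ValueError):
    """An argument or configuration value is outside its valid range."""


class SpecificationError(LincEqtlError, ValueError):
    """A simulation specification references unknown entities or is inconsistent."""


class InsufficientDataError(LincEqtlError, ValueError):
    """Too few observations to carry out the requested statistic."""


class MatchingError(LincEqtlError, RuntimeError):
    """Probe matching cannot be completed (candidate pool exhausted)."""


class DistanceError(LincEqtlError, ValueError):
    """Probe-SNP distance undefined (different chromosomes)."""


class PipelineError(LincEqtlError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
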