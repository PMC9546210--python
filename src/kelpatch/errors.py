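"""Exception hierarchy shared across the package."""


class KelpatchError(Exception):
    """Base class for all package-specific errors."""


class InvalidParamsError(KelpatchError, ValueError):
    """A parameter object violates its invariants."""


class InvalidBinsError(KelpatchError, ValueError):
    """Size-class bin edges are malformed (non-monotone, wrong length)."""


class DataError(KelpatchError, ValueError):
    """Input data violate the schema or a domain constraint."""


class DimensionError(KelpatchError, ValueError):
    """Array shapes are inconsistent."""


class SchemaError(DataError):
    """A required column is missing or mistyped in a tabular input."""


class ConfigError(KelpatchError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class InfeasibleError(KelpatchError, ValueError):
    """The requested fit is infeasible for the given data size."""


class PipelineError(KelpatchError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
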