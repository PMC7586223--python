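"""Exception hierarchy shared by all cbhkin modules."""


class CbhkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CbhkinError, ValueError):
    """A parameter violates its documented domain (sign, range, shape)."""


class ConsistencyError(CbhkinError, ValueError):
    """Cross-table inconsistency, e.g. an event referencing an unknown fibril."""


class EmptyDatasetError(CbhkinError, ValueError):
    """A filtering step left no data to analyse."""


class InsufficientDataError(CbhkinError, ValueError):
    """Too few observations for the requested fit."""


class TrajectoryFormatError(CbhkinError, ValueError):
    """A trajectory table is malformed (e.g. non-monotone frame numbers)."""


class IncompleteInputError(CbhkinError, ValueError):
    """A pipeline stage is missing a required input."""


class FitFailureError(CbhkinError, RuntimeError):
    """A nonlinear fit failed to converge or the data were degenerate.

    Carries optimizer diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PipelineStageError(CbhkinError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
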