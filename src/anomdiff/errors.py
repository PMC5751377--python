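"""Exception hierarchy.

All package errors derive from :class:`AnomdiffError` so callers can catch
broadly; the subclasses map onto the distinct failure contracts (bad
parameters, unparsable input, degenerate fits, simulation failure, pipeline
stage failure).
"""


class AnomdiffError(Exception):
    """Base class for all package errors."""


class ParameterError(AnomdiffError, ValueError):
    """A parameter violates its documented domain."""


class GenerationError(AnomdiffError, RuntimeError):
    """A stochastic generator could not produce a valid realization."""


class FormatError(AnomdiffError, ValueError):
    """An input file is malformed; the message names the offending location."""


class FitError(AnomdiffError, ValueError):
    """A regression could not be performed; the message names the offending lag."""


class StageError(AnomdiffError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
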