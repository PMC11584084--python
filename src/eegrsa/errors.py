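"""Exception hierarchy used across the package.

All package errors derive from :class:`EegRsaError` so callers can catch
validation problems (bad configs, malformed inputs) separately from genuine
runtime failures.
"""


class EegRsaError(Exception):
    """Base class for all errors raised by eegrsa."""


class InvalidConfigError(EegRsaError, ValueError):
    """A configuration value violates its documented range or invariant."""


class InvalidInputError(EegRsaError, ValueError):
    """A data input violates a precondition (shape, membership, emptiness)."""


class DegenerateModelError(EegRsaError, ValueError):
    """A model representation carries no usable variance."""


class EmptyRepresentationError(EegRsaError, ValueError):
    """No content word of an entity has an available embedding."""


class UndefinedCorrelationError(EegRsaError, ValueError):
    """A correlation is undefined because one input is constant."""


class PipelineStageError(EegRsaError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
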