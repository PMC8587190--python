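"""Exception types shared across the package."""


class EanrError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EanrError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(EanrError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero-power audio)."""


class TrainingDivergedError(EanrError, RuntimeError):
    """Optimization produced a non-finite loss."""


class StaleStoreError(EanrError, RuntimeError):
    """A transfer store does not match the base model it claims to extend."""


class MissingDependencyError(EanrError, ImportError):
    """An optional backend (e.g. an ITU PESQ implementation) is unavailable."""
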