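"""Exception hierarchy shared across the package."""


class KinoselectError(Exception):
    """Base class for all package errors."""


class ValidationError(KinoselectError):
    """Input violates a documented invariant (bad labels, values, targets...)."""


class MatrixIOError(KinoselectError):
    """A matrix or alias file could not be read or written."""


class UndefinedScoreError(KinoselectError):
    """Raised when an operation needs a score for a compound with no measured target."""
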