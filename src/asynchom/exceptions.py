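"""Exception hierarchy shared across the pipeline."""


class AsynchomError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(AsynchomError, ValueError):
    """An argument violates a precondition (non-positive count, bad range...)."""


class FormatError(AsynchomError, ValueError):
    """A file or table violates the expected format; names the offending cell."""


class CrossReferenceError(AsynchomError, ValueError):
    """Companion tables/trees disagree (unknown taxon, missing plot...)."""


class InvalidInputError(AsynchomError, ValueError):
    """Well-formed input that is invalid for the operation (all-zero row...)."""


class InvalidDesignError(AsynchomError, ValueError):
    """Grouping structure unusable for the test (singleton group, one level)."""


class InsufficientSamplesError(AsynchomError, ValueError):
    """Too few samples for the requested decomposition."""


class EmptyResultError(AsynchomError, ValueError):
    """An operation removed everything (e.g. a filter dropping all taxa)."""


class UndefinedValueError(AsynchomError, ArithmeticError):
    """A statistic is undefined for this input (zero null variance...)."""


class SimulationFailedError(AsynchomError, RuntimeError):
    """A conditioned simulation exhausted its retry budget."""

    def __init__(self, message: str, attempts: int | None = None):
        super().__init__(message)
        self.attempts = attempts


class ConvergenceError(AsynchomError, RuntimeError):
    """An optimizer failed to converge; carries the best point found."""

    def __init__(self, message: str, best=None, status: str | None = None):
        super().__init__(message)
        self.best = best
        self.status = status
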