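"""Exception hierarchy shared across the package."""


class JoigamError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(JoigamError):
    """A column-role schema is missing or inconsistent with the file."""


class CohortValidationError(JoigamError):
    """A subject table violates an invariant (labels, dimensions, NaNs)."""


class ConvergenceError(JoigamError):
    """An iterative solver failed to converge.

    The best iterate reached is attached as ``last_state`` so callers can
    inspect (and, for diagnostics, serialize) the partial result.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
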