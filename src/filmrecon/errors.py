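"""Exception types shared across the package."""


class FilmReconError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FilmReconError, ValueError):
    """An input violates a documented precondition or invariant."""


class InputDataError(FilmReconError, RuntimeError):
    """A file could not be read or decoded."""


class NumericalError(FilmReconError, RuntimeError):
    """A computation produced non-finite values."""
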