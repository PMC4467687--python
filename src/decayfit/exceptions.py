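"""Exception types shared across the package."""


class DecayfitError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(DecayfitError, ValueError):
    """A model parameter violates its domain (e.g. c outside [0, 1], tau <= 0)."""


class DegenerateWindowError(DecayfitError, ValueError):
    """The observation window has zero probability under the model (F(delta*m) = 0)."""


class EmptyHistogramError(DecayfitError, ValueError):
    """A histogram holds no photons (or none fall inside the observation window)."""


class NoSolutionError(DecayfitError, RuntimeError):
    """A moment-matching system has no acceptable solution."""


class UndefinedStatisticError(DecayfitError, ValueError):
    """A summary statistic was requested on an empty collection."""


class FormatError(DecayfitError, ValueError):
    """A text input file does not conform to the expected layout."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
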