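"""Exception types shared across the package."""


class UnwindfitError(ValueError):
    """Base class for all validation and domain errors raised by unwindfit."""


class ConfigurationError(UnwindfitError):
    """A model configuration (break positions, parameters) is malformed."""


class ModelDomainError(UnwindfitError):
    """An input lies outside the mathematical domain of a model map,
    e.g. an intensity at or below background passed to an inversion."""


class DataValidationError(UnwindfitError):
    """An input table or file violates the expected dialect or invariants.

    ``line`` carries the 1-based line number in the source file when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateDataError(UnwindfitError):
    """The data carry no usable signal (e.g. all intensities identical,
    so the decay rate is unidentifiable and SS_tot is zero)."""
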