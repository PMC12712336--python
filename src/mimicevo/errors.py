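"""Exception hierarchy shared across the package."""


class MimicevoError(Exception):
    """Base class for all package errors."""


class MeasurementError(MimicevoError):
    """A specimen measurement is invalid (e.g. nonpositive denominator)."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class UnscorableSpecimenError(MimicevoError):
    """Too many measurements missing to compute scores."""


class TreeError(MimicevoError):
    """Tree structure or parameter problem."""


class FitError(MimicevoError):
    """Model fitting failed in a non-recoverable way."""


class DataMismatchError(MimicevoError):
    """Tip data does not match the tree's tip set."""
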