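"""Exception hierarchy for mubkit."""


class MubkitError(Exception):
    """Base class for all mubkit errors."""


class InvalidParameterError(MubkitError, ValueError):
    """A domain parameter violates its stated invariant."""


class InvalidROIError(MubkitError, ValueError):
    """A region of interest is degenerate, empty or out of bounds."""


class InsufficientWidthError(InvalidROIError):
    """ROI is narrower than the physical trim width.

    Attributes
    ----------
    shortfall_mm : float
        How many millimetres of lateral extent are missing.
    """

    def __init__(self, message: str, shortfall_mm: float):
        super().__init__(message)
        self.shortfall_mm = shortfall_mm


class DegenerateDataError(MubkitError, ValueError):
    """Statistical input carries no usable signal (e.g. all-zero differences)."""


class SchemaError(MubkitError, ValueError):
    """A table is missing required columns or keys fail to join."""
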