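"""Exception hierarchy for fmcadti."""


class FmcaError(Exception):
    """Base class for all fmcadti errors."""


class MalformedSmilesError(FmcaError):
    """Raised when a SMILES string cannot be tokenized or is structurally invalid.

    Carries the 0-based offending position when known.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class InvalidSequenceError(FmcaError):
    """Raised for empty or non-alphabetic amino-acid sequences."""


class InvalidParameterError(FmcaError):
    """Raised when an operation parameter is out of its valid range."""


class InvalidInputError(FmcaError):
    """Raised for structurally invalid inputs (empty corpus, mismatched lengths...)."""


class ShapeError(FmcaError):
    """Raised on tensor shape mismatches in the model."""


class DivergenceError(FmcaError):
    """Raised when training produces a non-finite loss."""
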