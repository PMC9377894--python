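"""Exception hierarchy for the CRCD pipeline.

All errors derive from :class:`CRCDError` so callers can catch the whole
family; each also derives from the matching builtin (``ValueError`` /
``IOError``) so generic handling keeps working.
"""


class CRCDError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CRCDError, IOError):
    """A file could not be read or parsed as the requested format."""


class ValidationError(CRCDError, ValueError):
    """An input violates a data-type invariant (shape, range, NaN...)."""


class ParameterError(CRCDError, ValueError):
    """A parameter value is outside its admissible range."""


class DegenerateInputError(CRCDError, ValueError):
    """The input is too degenerate for the operation (e.g. a constant
    image handed to an automatic threshold)."""


class EmptySelectionError(CRCDError, ValueError):
    """A selection operation found nothing to select (no components,
    empty mask...)."""


class DivergenceError(CRCDError, ArithmeticError):
    """The level-set evolution produced non-finite values."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite level-set values at iteration {iteration}")
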