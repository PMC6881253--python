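"""Exception and warning types shared across the package."""


class PipflankError(Exception):
    """Base class for all package errors."""


class InvalidSpanError(PipflankError, ValueError):
    """Motif span has the wrong length for its declared class."""


class IncompleteMapError(PipflankError, ValueError):
    """A position map lacks coordinates required by the operation."""


class EmptyInputError(PipflankError, ValueError):
    """An operation requiring at least one entry received none."""


class UndefinedColumnError(PipflankError, ValueError):
    """A logo coordinate has zero (non-gap) observations."""


class InvalidResidueError(PipflankError, ValueError):
    """A sequence letter is outside the canonical amino-acid alphabet."""


class UnsupportedNucleusError(PipflankError, ValueError):
    """The random-coil reference does not cover the requested nucleus."""


class ShiftConsistencyError(PipflankError, ValueError):
    """Observed shift table disagrees with the sequence it is indexed into."""


class TrackAlignmentError(PipflankError, ValueError):
    """Disorder predictor tracks for one protein differ in length."""


class DegenerateRegressionError(PipflankError, ValueError):
    """Regression input has too few points or zero variance."""


class FitConvergenceError(PipflankError, RuntimeError):
    """A nonlinear fit failed to converge or is structurally unidentifiable."""


class TableFormatError(PipflankError, ValueError):
    """A delimited input table violates its column contract."""


class UnreliableFitWarning(UserWarning):
    """Fitted parameters fall outside the range the data can support."""


class TooFastKineticsWarning(UserWarning):
    """Fitted rate constants exceed what the injection schedule can resolve."""
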