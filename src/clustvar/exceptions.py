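"""Exception hierarchy for clustvar."""


class ClustvarError(Exception):
    """Base class for all clustvar errors."""


class PanelFormatError(ClustvarError):
    """The input file does not have the expected columns or layout."""


class PanelParseError(ClustvarError):
    """A cell in the input file could not be parsed as a number."""


class PanelValidationError(ClustvarError):
    """The panel violates a structural invariant (e.g. duplicate times)."""


class ParameterError(ClustvarError):
    """An argument is outside its admissible range."""


class InsufficientDataError(ClustvarError):
    """Too few lagged pairs to estimate the requested model."""


class RankDeficiencyError(ClustvarError):
    """The regressor cross-product matrix is numerically singular."""


class InfeasiblePartitionError(ClustvarError):
    """A partition with the requested shape cannot exist (e.g. I < K)."""


class FitFailedError(ClustvarError):
    """An optimization run could not be completed."""


class GenerationError(ClustvarError):
    """The simulator failed to produce an admissible draw."""
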