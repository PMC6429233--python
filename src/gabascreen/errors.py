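"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`GabascreenError` so callers can
catch pipeline failures without masking programming errors.
"""


class GabascreenError(Exception):
    """Base class for all pipeline errors."""


class LibraryError(GabascreenError):
    """Unreadable library file or a library with zero valid records."""


class PropertyError(GabascreenError):
    """The chemistry backend failed to compute properties for a compound."""


class ConformerError(GabascreenError):
    """3D embedding failed for every attempt."""


class ClassificationError(GabascreenError):
    """Unknown activity measure or invalid threshold table."""


class ConversionError(GabascreenError):
    """An activity measure that cannot be converted to pIC50."""


class ParameterError(GabascreenError):
    """An operation was called with parameters outside its contract."""


class DecoyShortageError(GabascreenError):
    """Not enough eligible decoy candidates for an active.

    Attributes
    ----------
    active_id : str
        The active that could not be served.
    shortfall : int
        How many decoys were missing.
    """

    def __init__(self, active_id: str, shortfall: int, message: str | None = None):
        self.active_id = active_id
        self.shortfall = shortfall
        super().__init__(
            message
            or f"decoy shortage for active {active_id!r}: {shortfall} more eligible candidates needed"
        )


class UndefinedStatisticError(GabascreenError):
    """A screening statistic is undefined for the given counts (e.g. D = 0)."""


class EvaluationError(GabascreenError):
    """Hypothesis evaluation called with empty actives or decoys."""


class SingularFitError(GabascreenError):
    """Rank-deficient design matrix in a regression fit."""


class FitSizeError(GabascreenError):
    """Too few training points for the requested regression."""


class PoseError(GabascreenError):
    """A compound lacks the conformer/pose required by an energy backend."""


class MissingScoreError(GabascreenError):
    """A compound reached the docking-score stage without a score."""

    def __init__(self, compound_id: str):
        self.compound_id = compound_id
        super().__init__(f"no docking score available for compound {compound_id!r}")


class GenerationError(GabascreenError):
    """A synthetic-data generator exhausted its attempt budget."""
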