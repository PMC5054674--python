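"""Exception hierarchy for the lamorph pipeline.

All lamorph-specific failures derive from :class:`LamorphError` so callers
can catch pipeline errors without masking programming errors.
"""


class LamorphError(Exception):
    """Base class for all lamorph errors."""


class InvalidInputError(LamorphError):
    """Input data violates a precondition (non-finite values, bad shapes)."""


class ShapeMismatchError(LamorphError):
    """Landmark configurations with incompatible dimensions were combined."""


class DegenerateConfigurationError(LamorphError):
    """A configuration collapses to a point (zero centroid size)."""


class InvalidEventsError(LamorphError):
    """Electromechanical event annotations violate their required ordering."""


class OutOfRangeError(LamorphError):
    """A query time falls outside the observed time span (no extrapolation)."""


class IncompleteTrajectoryError(LamorphError):
    """Deformation scores are missing at one or more homologous times."""


class UndefinedOrientationError(LamorphError):
    """Trajectory orientation is undefined (coincident anchor landmarks)."""


class UnderDeterminedAlignmentError(LamorphError):
    """Too few anchor landmarks to estimate a similarity transform."""


class InsufficientDataError(LamorphError):
    """Fewer observations than the statistical operation requires."""


class InvalidDesignError(LamorphError):
    """A statistical design is unusable (single group, constant response)."""


class InvalidSpecError(LamorphError):
    """A cohort specification is internally inconsistent or infeasible."""
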