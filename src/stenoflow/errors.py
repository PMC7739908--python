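"""Exception hierarchy for stenoflow.

All domain errors derive from :class:`StenoflowError` so callers can catch
one base class at pipeline boundaries.
"""


class StenoflowError(Exception):
    """Base class for all stenoflow errors."""


class ValidationError(StenoflowError, ValueError):
    """A parameter violates a geometric or physical invariant.

    The message names the offending field.
    """


class ResolutionError(StenoflowError, ValueError):
    """Grid spacing too coarse for the requested geometry."""


class OffsetError(StenoflowError, ValueError):
    """Wall-offset distance leaves the lumen."""


class SolverError(StenoflowError, RuntimeError):
    """Flow solve failed to converge; carries the residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or []


class StateError(StenoflowError, RuntimeError):
    """Operation requested on an unconverged or otherwise invalid state."""


class GeometryError(StenoflowError, ValueError):
    """Sample points leave the fluid domain."""


class WindowError(StenoflowError, ValueError):
    """Averaging window empty or too short."""


class TrajectoryError(StenoflowError, ValueError):
    """Cell trajectories cannot be linked across snapshots."""


class ConfigurationError(StenoflowError, ValueError):
    """A required configuration value (e.g. a cell volume) is missing."""


class AlignmentError(StenoflowError, ValueError):
    """Time or space supports of two records do not overlap."""


class AnnotationError(StenoflowError, ValueError):
    """Corner annotation inconsistent with the image frame."""


class DegenerateProfileError(StenoflowError, ValueError):
    """Intensity profile carries no contrast; no peak is defined."""


class SpecError(StenoflowError, ValueError):
    """A synthetic-data specification is infeasible."""
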