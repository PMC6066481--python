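"""Exception hierarchy for markerpipe.

Every error raised on purpose derives from :class:`MarkerPipeError` so callers
can catch pipeline failures without masking programming errors.
"""


class MarkerPipeError(Exception):
    """Base class for all markerpipe errors."""


class InvalidConfigError(MarkerPipeError, ValueError):
    """A generator or model configuration violates its invariants."""


class InvalidInputError(MarkerPipeError, ValueError):
    """An input value is outside the operation's domain."""


class InsufficientDataError(MarkerPipeError, ValueError):
    """Too few observations (or dilution levels) for the requested fit."""


class AlignmentError(MarkerPipeError, ValueError):
    """Sample identifiers do not line up between two inputs."""

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)


class CurveOrientationError(MarkerPipeError, ValueError):
    """A standard curve has a non-negative slope (Cq must fall with copies)."""


class UndefinedNcnError(MarkerPipeError, ValueError):
    """Control-gene copies are zero; the sample is non-evaluable."""


class DegenerateLabelsError(MarkerPipeError, ValueError):
    """A binary-outcome operation received a single class."""


class DegenerateGroupsError(MarkerPipeError, ValueError):
    """A two-sample test received fewer than two non-empty groups."""


class NoEventsError(MarkerPipeError, ValueError):
    """No events of the requested cause are present."""


class SeparationError(MarkerPipeError, RuntimeError):
    """Complete or quasi-complete separation in a regression fit."""

    def __init__(self, message, covariate=None):
        super().__init__(message)
        self.covariate = covariate


class ConvergenceError(MarkerPipeError, RuntimeError):
    """An iterative fit failed to converge."""


class DataIntegrityError(MarkerPipeError, ValueError):
    """Clinical dates are mutually inconsistent (e.g. relapse before CR)."""

    def __init__(self, message, patient_ids=()):
        super().__init__(message)
        self.patient_ids = list(patient_ids)


class UndefinedTestError(MarkerPipeError, ValueError):
    """A contingency-table test is undefined (empty margin)."""
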