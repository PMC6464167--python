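"""Exception hierarchy for vegsynth.

Every invariant violation raises a distinct, named error so callers can
react to (and tests can assert) the specific failure mode.
"""


class VegsynthError(Exception):
    """Base class for all vegsynth errors."""


class PanelValidationError(VegsynthError):
    """A panel or configuration invariant is violated."""


class DuplicateRecordError(PanelValidationError):
    """An outcome file contains a duplicated (unit, year) record."""


class NonNumericDataError(PanelValidationError):
    """A value that must be numeric could not be parsed as a number."""


class UnitAlignmentError(PanelValidationError):
    """Outcome and predictor files do not cover the same unit set."""


class MissingDataError(PanelValidationError):
    """A required cell is missing (the matching algebra has no
    missing-data semantics; imputation is the caller's job)."""


class ZeroImportanceError(VegsynthError):
    """An importance (V) vector is all zero and cannot be normalized."""


class DegenerateInputError(VegsynthError):
    """An input is structurally degenerate (empty table, zero baseline...)."""


class ConvergenceError(VegsynthError):
    """The nested optimizer failed to produce a finite solution after all
    restarts."""


class NoAcceptedFitsError(VegsynthError):
    """A placebo study ended with zero plausible fits; averaging would be
    meaningless, so this is raised instead of returning an empty table."""
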