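"""Exception taxonomy for the ovismap package.

Every recoverable domain failure raises a subclass of :class:`OvismapError`
so callers (and the CLI) can distinguish domain problems from bugs.
"""


class OvismapError(Exception):
    """Base class for all domain errors raised by ovismap."""


class FormatError(OvismapError):
    """A binary or text input does not conform to its declared format."""


class EmptyPanelError(OvismapError):
    """A genotype panel with zero samples or zero variants was supplied."""


class UnknownVariantError(OvismapError, KeyError):
    """A requested rs_id is absent from a panel or reference table."""


class DegenerateVariantError(OvismapError):
    """A variant has zero dosage variance where variation is required."""


class MissingColumnError(OvismapError):
    """A required summary-statistics column is absent from the input."""


class DegenerateSEError(OvismapError):
    """A non-positive or underivable standard error."""


class InvalidPError(OvismapError):
    """A p-value outside the open interval (0, 1) where one is required."""


class IncompleteRecordError(OvismapError):
    """A record lacks the fields needed to complete its statistics."""


class CheckNotApplicableError(OvismapError):
    """A QC check cannot run on this study (e.g. no allele frequencies)."""


class EmptyReportError(OvismapError):
    """render_report was called with no check results."""


class DuplicateStudyError(OvismapError):
    """A study_key is already registered in the store."""


class QCNotPassedError(OvismapError):
    """Registration requires QC but the study did not pass."""


class UnknownStudyError(OvismapError, KeyError):
    """A study_key is not present in the store."""


class InsufficientOverlapError(OvismapError):
    """Fewer than the minimum shared SNPs between two studies in a region."""


class DegeneratePatternError(OvismapError):
    """A z-score vector has zero variance, so no correlation is defined."""


class MissingMarkerError(OvismapError):
    """A scoring marker is absent from the genotype panel."""


class AlleleMismatchError(OvismapError):
    """A marker's stated effective allele matches neither panel allele."""


class DegeneratePredictorError(OvismapError):
    """A regression predictor (e.g. BV) is constant."""


class DegenerateBVError(OvismapError):
    """All breeding values are equal; no top quartile exists."""
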