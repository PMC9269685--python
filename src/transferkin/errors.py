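"""Exception hierarchy.

Every error raised by the package derives from :class:`TransferKinError`, so
callers (and the batch pipeline) can catch one type and record the failure
per trial instead of aborting a whole session.
"""


class TransferKinError(Exception):
    """Base class for all transferkin errors."""


class VocabularyError(TransferKinError):
    """A joint name does not belong to the declared sensor's vocabulary."""


class FormatError(TransferKinError):
    """A recording file violates the expected CSV layout or ordering."""


class AlignmentError(TransferKinError):
    """Paired recordings cannot be matched on a common time base."""


class MappingError(TransferKinError):
    """No joint mapping exists for the requested sensor or side."""


class SegmentationError(TransferKinError):
    """Lift-phase detection failed."""


class NoPlateauError(SegmentationError):
    """The trajectory has no resolvable pre-lift / landing plateau."""


class NoTransferError(SegmentationError):
    """Net pelvis displacement is below the noise floor; no transfer present."""


class MissingDataError(SegmentationError):
    """A gap of missing samples is too long to interpolate safely."""


class DegenerateGeometryError(TransferKinError):
    """A zero-length or collapsed vector makes an angle undefined."""


class ReliabilityError(TransferKinError):
    """A reliability statistic cannot be computed from the given design."""


class UndefinedICCError(ReliabilityError):
    """Zero total variance: the intraclass correlation is undefined."""


class AgreementError(TransferKinError):
    """Score tables are misaligned or malformed."""
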