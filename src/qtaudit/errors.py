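"""Exception taxonomy shared across the measurement pipeline."""


class QTAuditError(Exception):
    """Base class for all pipeline errors."""


class UnusableRecordError(QTAuditError):
    """The record contains no usable beats (too short, pure noise, no QRS)."""


class UnmeasurableTError(QTAuditError):
    """No T-wave limb steep enough to draw a tangent (flat T, tangent parallel
    to baseline)."""


class ExcludedRecordError(QTAuditError):
    """The record is excluded from analysis by protocol (e.g. bigeminal
    rhythm, no measurable lead)."""
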