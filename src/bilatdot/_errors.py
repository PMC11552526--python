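"""Exception hierarchy shared across the pipeline stages."""


class BilatDotError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BilatDotError, ValueError):
    """A parameter or configuration field is outside its admissible range."""


class RangeError(BilatDotError, IndexError):
    """A source, detector, or channel index is out of range."""


class InsufficientDataError(BilatDotError, ValueError):
    """A block is too short for the requested operation (e.g. truncation)."""


class FormatError(BilatDotError, ValueError):
    """An on-disk cohort container violates its manifest or schema."""


class DegenerateDataError(BilatDotError, ValueError):
    """A statistic needed by an operation vanishes (zero spread, single class...)."""


class ConsistencyError(BilatDotError, ValueError):
    """Two objects that must agree in shape or provenance do not."""


class StratificationError(BilatDotError, ValueError):
    """A class stratum is too small to honour the requested split sizes."""


class UndefinedAUCError(DegenerateDataError):
    """ROC analysis was requested with only one class present."""
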