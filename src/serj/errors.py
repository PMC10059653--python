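"""Exception hierarchy shared across the pipeline."""


class SerjError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SerjError, ValueError):
    """An operation was called with arguments outside its contract."""


class FormatError(SerjError, ValueError):
    """An input file violates the expected on-disk format."""


class SingularityError(SerjError, ArithmeticError):
    """The hardware-calibration transform hit its pole (raw sample equals d)."""


class DegenerateSegmentError(SerjError, ValueError):
    """A constant segment cannot be min-max normalized."""


class DegenerateThresholdError(SerjError, ValueError):
    """A feature stream's reference span is constant, so no threshold exists."""


class InsufficientBeatsError(SerjError, ValueError):
    """Fewer than two pulse beats were detectable in the analysis scope."""


class StratificationError(SerjError, ValueError):
    """A class is absent from (or too small for) the stratified training split."""
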