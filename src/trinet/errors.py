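"""Exception hierarchy shared across the toolkit."""


class TrinetError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TrinetError):
    """A file could not be parsed as the expected format."""


class UnsupportedRankError(FormatError):
    """A volume file has more dimensions than the pipeline supports."""


class GeometryError(TrinetError):
    """Two objects that must share a voxel grid do not."""


class ValidationError(TrinetError):
    """An argument violates a documented precondition."""


class CapacityError(ValidationError):
    """A request exceeds what the data can support (e.g. clusters > frames)."""


class AlignmentError(ValidationError):
    """Locations or gene identifiers of two panels do not line up."""


class UndefinedEffectError(TrinetError):
    """A statistic is undefined for the given data (zero variance etc.)."""


class InsufficientExperimentsError(ValidationError):
    """Too few tracer experiments to correlate profiles."""
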