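"""Exception hierarchy shared across the package."""


class Mil3dError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(Mil3dError):
    """A structural-parameter table violates the expected 64 x 6 layout."""


class InvalidSequenceError(Mil3dError):
    """A DNA sequence contains characters outside A/C/G/T."""


class ProbeParseError(Mil3dError):
    """A probe table row could not be parsed."""


class ConsistencyError(Mil3dError):
    """Inputs disagree on k, feature length or model metadata."""


class TrainingError(Mil3dError):
    """Training preconditions violated (e.g. a single-class training set)."""


class UndefinedStatisticError(Mil3dError):
    """A statistic is undefined for the given input (single class, zero variance)."""
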