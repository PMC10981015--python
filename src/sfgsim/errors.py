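"""Exception types shared across the package."""


class SfgError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SfgError, ValueError):
    """A parameter violates a documented precondition."""


class InfeasibleSpecError(SfgError, ValueError):
    """A stimulus specification cannot be realized on the frequency grid."""


class NormalizationError(SfgError, ValueError):
    """Audio normalization would clip the waveform."""


class IncompleteAudiogramError(SfgError, ValueError):
    """An audiogram is missing required frequencies or ears."""


class MissingCellError(SfgError, ValueError):
    """A behavioral design cell has no trials."""


class UndefinedStatisticError(SfgError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class EmptyConditionError(SfgError, ValueError):
    """No accepted epochs remain in a condition."""
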