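"""Exception hierarchy for the screening engine."""


class CVDScreenError(Exception):
    """Base class for all engine errors."""


class InvalidConeExcitationError(CVDScreenError):
    """Cone excitation with L+M = 0 cannot be projected to chromaticity."""


class UnderdeterminedConversionError(CVDScreenError):
    """Chromaticity without a luminance cannot be lifted to cone space."""


class GamutViolationError(CVDScreenError):
    """Requested cone excitation falls outside the device's linear RGB cube."""


class InvalidSaturationError(CVDScreenError):
    """Saturation outside [0, 1]."""


class InvalidProfileError(CVDScreenError):
    """Device profile violates its invariants."""


class SaturationOverflowError(CVDScreenError):
    """Active staircase saturation above the 0.9 display ceiling."""


class ProtocolViolationError(CVDScreenError):
    """Tap reported for an inactive staircase, or tap after completion."""


class InsufficientDataError(CVDScreenError):
    """Session below the minimum-valid-trial floor."""


class UnfittableDataError(CVDScreenError):
    """Fewer than two distinct stimulus levels with observations."""


class EmptyDataError(CVDScreenError):
    """No observations at all."""


class InvalidLevelError(CVDScreenError):
    """Performance level outside (0, 1)."""


class InvalidThresholdError(CVDScreenError):
    """Nonpositive threshold passed to the ratio metric."""


class InvalidCountError(CVDScreenError):
    """Negative error count for the reference-test grouping."""


class UndefinedMetricError(CVDScreenError):
    """Sensitivity/specificity requested with an empty reference class."""


class NonterminatingSessionError(CVDScreenError):
    """Simulated session exceeded the trial budget without completing."""


class FormatError(CVDScreenError):
    """Malformed session/profile/config file."""
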