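"""Exception hierarchy for playfall.

All parameter-validation failures derive from :class:`InvalidParameterError`
(a ``ValueError``), all runtime/solver failures from ``PlayfallError`` via
``RuntimeError`` mixins, so callers can catch either the narrow or the broad
class.
"""


class PlayfallError(Exception):
    """Base class for all playfall errors."""


class InvalidParameterError(PlayfallError, ValueError):
    """A parameter violates its documented precondition."""


class UnitError(InvalidParameterError):
    """A signal carries the wrong unit tag for the requested operation."""


class AlignmentError(InvalidParameterError):
    """Triaxial channels do not share time base, length or unit."""


class BottomOutError(PlayfallError, RuntimeError):
    """Indentation reached the surfacing layer thickness.

    The reduced-order contact law is undefined past full compression; use a
    stiffer loading curve or a thicker layer.
    """


class DivergenceError(PlayfallError, RuntimeError):
    """The drop integration failed to reach headform separation."""


class CalibrationError(PlayfallError, RuntimeError):
    """Scale calibration could not bracket or reach the target response."""


class BracketError(PlayfallError, RuntimeError):
    """A root/threshold search found a non-monotone or unbracketable response."""
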