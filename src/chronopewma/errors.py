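"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ChronoPewmaError`, so callers can catch one type at an orchestration
boundary and still distinguish data problems from infeasible requests.
"""


class ChronoPewmaError(Exception):
    """Base class for all errors raised by chronopewma."""


class CurveParseError(ChronoPewmaError):
    """A calibration-curve file contains a malformed record."""

    def __init__(self, path, line_number, message):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class InsufficientDataError(ChronoPewmaError):
    """Fewer usable records than the operation requires."""


class DomainError(ChronoPewmaError):
    """A query falls outside the supported domain (no extrapolation)."""


class IncompatibleDateError(ChronoPewmaError):
    """A radiocarbon date has essentially zero likelihood anywhere on the curve span."""


class InfeasibleOrderingError(ChronoPewmaError):
    """No strictly ordered configuration of calendar ages exists for the given densities."""


class CalibrationFailureError(ChronoPewmaError):
    """The target covariate-count correlation is unreachable by tuning delta."""

    def __init__(self, target, achieved):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"target correlation {target:.3f} unreachable; "
            f"maximum achieved {achieved:.3f}"
        )


class DegenerateDataError(ChronoPewmaError):
    """Input data carry no information for the requested fit (e.g. all-zero counts)."""
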