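"""Exception hierarchy.

Every error raised by the package derives from :class:`MitoflightError` so
callers (and the CLI) can catch one base class and map error classes to
exit codes.
"""

from __future__ import annotations


class MitoflightError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(MitoflightError, ValueError):
    """A parameter or field failed validation.

    Parameters
    ----------
    field : name of the offending field.
    message : human-readable explanation.
    """

    exit_code = 2

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InsufficientDataError(MitoflightError):
    """Too few frames / samples / rows for the requested operation."""

    exit_code = 3


class NoTakeoffDetectedError(MitoflightError):
    """No frame exceeded the onset speed threshold with a full window after it."""

    exit_code = 4


class WindowSpansEventError(MitoflightError):
    """A flux-estimation window contains a titration event."""

    exit_code = 5


class SegmentTooShortError(MitoflightError):
    """A protocol segment is shorter than settle + window seconds."""

    exit_code = 5

    def __init__(self, state: str, length: float, required: float):
        self.state = state
        super().__init__(
            f"segment for state {state!r} lasts {length:.1f} s; "
            f"need at least {required:.1f} s (settle + window)"
        )


class ProtocolError(MitoflightError):
    """The titration event sequence violates the protocol invariants."""

    exit_code = 5


class AnoxiaError(MitoflightError):
    """A simulated chamber would run out of oxygen before the protocol ends."""

    exit_code = 6


class UndefinedRatioError(MitoflightError):
    """A flux control ratio is undefined (non-positive denominator state)."""

    exit_code = 6


class DegenerateVarianceError(MitoflightError):
    """A variable needed by a statistical routine has zero variance."""

    exit_code = 7

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"variable {name!r} has zero variance")


class CollinearityError(MitoflightError):
    """The design matrix is rank deficient."""

    exit_code = 7


class UnattainableRSquaredError(MitoflightError):
    """The requested model R-squared cannot be realised.

    Carries the attainable bound so callers can adjust.
    """

    exit_code = 7

    def __init__(self, message: str, bound: float):
        self.bound = bound
        super().__init__(f"{message} (attainable bound: {bound:.4f})")


class ParseError(MitoflightError):
    """A file failed schema validation; reports file and location."""

    exit_code = 8

    def __init__(self, path, message: str, row: int | None = None):
        self.path = str(path)
        self.row = row
        loc = f"{path}" + (f", row {row}" if row is not None else "")
        super().__init__(f"{loc}: {message}")
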