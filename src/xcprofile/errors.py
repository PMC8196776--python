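"""Exception hierarchy shared by all xcprofile modules.

Per-athlete analysis failures are raised as typed exceptions; the
orchestration layer catches them and degrades to flags so that one bad
test never drops an athlete silently.
"""


class XCProfileError(Exception):
    """Base class for all package errors."""


# --- lactate step tests -----------------------------------------------------

class InsufficientStages(XCProfileError):
    """Too few step-test stages for the requested polynomial degree."""


class DegenerateDesign(XCProfileError):
    """Rank-deficient design matrix (duplicate powers / durations)."""


class NotReached(XCProfileError):
    """The fitted lactate curve never attains the target concentration."""


class AlreadyExceeded(XCProfileError):
    """The fitted curve is above the target concentration at the first stage."""


class UndeterminedLow(XCProfileError):
    """First stage already at or above baseline + 1 mmol/L."""


class UndeterminedHigh(XCProfileError):
    """No stage reaches baseline + 1 mmol/L."""


class DegenerateChord(XCProfileError):
    """Lactate profile is collinear; no perpendicular-distance maximiser."""


class UnusableProtocol(XCProfileError):
    """Athlete's lactate at the first stage already exceeds the stop rule."""


# --- power profile ----------------------------------------------------------

class InsufficientSamples(XCProfileError):
    """Power stream shorter than the requested window."""


class InsufficientPoints(XCProfileError):
    """Fewer than three distinct durations for the critical-power fit."""


class InvalidEndpoint(XCProfileError):
    """Graded-test endpoint violates its invariants (e.g. t >= stage duration)."""


# --- anthropometry ----------------------------------------------------------

class MissingMeasurement(XCProfileError):
    """A required anthropometric site is absent; message names the site."""


class ConstantsChecksumError(XCProfileError):
    """Packaged fractionation constants failed their integrity check."""


# --- statistics / pipeline --------------------------------------------------

class SampleTooSmall(XCProfileError):
    """Fewer complete cases than the analysis minimum."""


class MissingPredictor(XCProfileError):
    """Prediction requested without all model predictors supplied."""


class ConfigError(XCProfileError):
    """Invalid generator or pipeline configuration."""
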