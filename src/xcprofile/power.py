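"""Field power-profile reduction, critical power and maximal aerobic power.

Covers the mean-maximal-power reduction of 1 Hz streams, the linear
power-vs-1/t critical-power model (intercept = CP in W, slope = W' in
joules), the end-test maximal aerobic power equation
``W_f + t/60 * increment`` and the RPE/heart-rate validity rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateDesign,
    InsufficientPoints,
    InsufficientSamples,
    InvalidEndpoint,
)

EFFORT_KEYS = ("sprint6s", "p30s", "p1min", "p5min", "p10min")
CP_DURATIONS_S = (60.0, 300.0, 600.0)


@dataclass
class EffortSet:
    """Per-effort mean powers for one athlete (any subset present)."""

    athlete_id: str
    sprint6s: Optional[float] = None
    p30s: Optional[float] = None
    p1min: Optional[float] = None
    p5min: Optional[float] = None
    p10min: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key in EFFORT_KEYS:
            value = getattr(self, key)
            if value is not None and value <= 0:
                raise ValueError(f"{key} power must be positive")
        if (self.p5min is not None and self.p10min is not None
                and self.p5min < self.p10min):
            self.flags.append("p5min_below_p10min")

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {key: getattr(self, key) for key in EFFORT_KEYS}


@dataclass
class CPModel:
    """Fitted hyperbolic power-duration model."""

    cp_w: float
    w_prime_j: float
    r_squared: float
    points: List[Tuple[float, float]]  # (duration s, mean power W)

    @property
    def w_prime_kj(self) -> float:
        return self.w_prime_j / 1000.0

    def predict(self, t_s: float | np.ndarray) -> float | np.ndarray:
        return self.cp_w + self.w_prime_j / np.asarray(t_s, dtype=float)


@dataclass
class GradedTestEndpoint:
    """Endpoint of the 25 W / 1 min graded maximal test."""

    athlete_id: str
    last_completed_w: float
    seconds_into_stage: float
    stage_increment_w: float = 25.0
    stage_duration_s: float = 60.0
    max_rpe: Optional[float] = None
    max_hr_bpm: Optional[float] = None
    age_yr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.last_completed_w <= 0:
            raise InvalidEndpoint("last completed workload must be positive")
        if not 0 <= self.seconds_into_stage < self.stage_duration_s:
            raise InvalidEndpoint(
                "seconds into the uncompleted stage must lie in "
                f"[0, {self.stage_duration_s})"
            )
        # note: no absolute grid check on last_completed_w — the stage
        # grid offset depends on the athlete-specific start load


def mean_max_power(stream: Sequence[float], window_s: int) -> float:
    """Highest mean power over any contiguous window of ``window_s`` samples.

    The stream is sampled at 1 Hz, so a window of ``window_s`` seconds is
    ``window_s`` consecutive samples.
    """
    x = np.asarray(stream, dtype=float)
    if window_s < 1:
        raise ValueError("window must be at least 1 s")
    if len(x) < window_s:
        raise InsufficientSamples(
            f"stream of {len(x)} samples shorter than {window_s} s window"
        )
    cumsum = np.concatenate(([0.0], np.cumsum(x)))
    sums = cumsum[window_s:] - cumsum[:-window_s]
    return float(np.max(sums) / window_s)


def fit_cp(points: Iterable[Tuple[float, float]]) -> CPModel:
    """Least-squares fit of mean power on inverse duration.

    ``points`` are (duration s, mean power W) pairs — conventionally the
    60 s, 5 min and 10 min efforts.  The intercept is CP (W) and the
    slope is W' (J, i.e. W*s).
    """
    pts = [(float(t), float(p)) for t, p in points]
    if len(pts) < 3:
        raise InsufficientPoints("critical-power fit needs >= 3 points")
    t = np.array([p[0] for p in pts])
    p = np.array([p[1] for p in pts])
    if len(np.unique(t)) != len(t):
        raise DegenerateDesign("duplicate effort durations")
    design = np.column_stack([np.ones_like(t), 1.0 / t])
    coef, _, _, _ = np.linalg.lstsq(design, p, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((p - fitted) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CPModel(cp_w=float(coef[0]), w_prime_j=float(coef[1]),
                   r_squared=r2, points=pts)


def kuipers_po_vo2max(endpoint: GradedTestEndpoint) -> float:
    """Maximal aerobic power from the last completed workload.

    ``W_f + t/stage_duration * increment`` with the default 25 W / 60 s
    stages; the endpoint constructor already rejects t >= stage duration.
    """
    return float(
        endpoint.last_completed_w
        + endpoint.seconds_into_stage / endpoint.stage_duration_s
        * endpoint.stage_increment_w
    )


def check_test_validity(endpoint: GradedTestEndpoint) -> str:
    """Maximal-test validity: RPE > 9 and HR > 80% of (220 - age).

    Returns ``"valid"``, ``"invalid"`` or ``"unknown"`` (missing fields).
    Invalid tests are flagged, never dropped.
    """
    if endpoint.max_rpe is None or endpoint.max_hr_bpm is None \
            or endpoint.age_yr is None:
        return "unknown"
    hr_threshold = 0.8 * (220.0 - endpoint.age_yr)
    ok = endpoint.max_rpe > 9.0 and endpoint.max_hr_bpm > hr_threshold
    return "valid" if ok else "invalid"


def normalise_markers(markers: Dict[str, Optional[float]],
                      mass_kg: float) -> Dict[str, Optional[float]]:
    """Divide each absolute marker (W) by body mass (kg); None passes through."""
    if mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return {k: (None if v is None else v / mass_kg) for k, v in markers.items()}
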