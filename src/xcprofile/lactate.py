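"""Lactate step-test curve fitting and threshold extraction.

A step test is an ordered series of constant-power stages with an
end-of-stage capillary lactate measurement plus a resting baseline
sample.  Five power markers are derived per athlete:

* ``po_lt1``  — last stage before measured lactate rises 1 mmol/L above
  baseline (stage-discrete rule on observed values).
* ``po_lt2``  — power of maximal acceleration (argmax of the second
  derivative) of a degree-4 least-squares lactate curve.
* ``po_x2`` / ``po_x4`` — power at fixed 2 / 4 mmol/L on a degree-3 curve.
* ``po_dmax`` — power of maximal perpendicular distance between the
  degree-3 curve and the chord joining the first and last measurements.

Curve-based markers are accurate to better than 0.01 W relative to the
fitted polynomial; reported powers are exact optimiser/root locations,
not grid-rounded values, so that curve(po_at_fixed_lactate(c)) == c to
numerical precision.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import (
    AlreadyExceeded,
    DegenerateChord,
    DegenerateDesign,
    InsufficientStages,
    NotReached,
    UndeterminedHigh,
    UndeterminedLow,
)

RESOLUTION_W = 0.01  # guaranteed accuracy of curve-based markers


@dataclass(frozen=True)
class Stage:
    """One completed step-test stage."""

    power_w: float
    lactate_mmol_l: float
    hr_bpm: Optional[float] = None
    rpe: Optional[float] = None


@dataclass
class StepTest:
    """One athlete's lactate step test: baseline sample + ordered stages."""

    athlete_id: str
    baseline_lactate: float
    stages: List[Stage]

    def __post_init__(self) -> None:
        powers = [s.power_w for s in self.stages]
        if any(b <= a for a, b in zip(powers, powers[1:])):
            raise ValueError("stage powers must be strictly increasing")
        if any(s.lactate_mmol_l <= 0 for s in self.stages):
            raise ValueError("stage lactate values must be positive")
        if self.baseline_lactate <= 0:
            raise ValueError("baseline lactate must be positive")

    @property
    def powers(self) -> np.ndarray:
        return np.array([s.power_w for s in self.stages], dtype=float)

    @property
    def lactates(self) -> np.ndarray:
        return np.array([s.lactate_mmol_l for s in self.stages], dtype=float)


@dataclass
class LactateCurve:
    """Least-squares polynomial lactate-vs-power curve on a stage domain.

    ``coefficients`` are in ascending power order; the curve is only
    meaningful on ``[p_min, p_max]`` (first and last stage powers).
    """

    degree: int
    coefficients: np.ndarray
    p_min: float
    p_max: float
    rss: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("need degree+1 coefficients")

    def __call__(self, power: float | np.ndarray) -> float | np.ndarray:
        return npoly.polyval(power, self.coefficients)

    def derivative(self, order: int = 1) -> np.ndarray:
        return npoly.polyder(self.coefficients, order)


@dataclass
class Lt2Result:
    power_w: float
    boundary: bool = False  # second derivative maximised at a domain endpoint


# reason codes used when a threshold cannot be determined
@dataclass
class ThresholdSet:
    """All five power markers for one athlete, with undetermined flags."""

    athlete_id: str
    po_lt1: Optional[float] = None
    po_lt2: Optional[float] = None
    po_x2: Optional[float] = None
    po_x4: Optional[float] = None
    po_dmax: Optional[float] = None
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "po_lt1_w": self.po_lt1,
            "po_lt2_w": self.po_lt2,
            "po_x2_w": self.po_x2,
            "po_x4_w": self.po_x4,
            "po_dmax_w": self.po_dmax,
            "flags": ";".join(f"{k}:{v}" for k, v in sorted(self.flags.items())),
        }


def fit_lactate_curve(test: StepTest, degree: int = 3) -> LactateCurve:
    """Ordinary least-squares polynomial fit of lactate on power.

    The resting baseline sample is excluded: it was not taken at a work
    rate.  Raises :class:`InsufficientStages` when there are fewer than
    ``degree + 1`` stages and :class:`DegenerateDesign` on duplicate
    powers.
    """
    if degree not in (3, 4):
        raise ValueError("degree must be 3 or 4")
    p = test.powers
    c = test.lactates
    if len(p) < degree + 1:
        raise InsufficientStages(
            f"{len(p)} stages cannot support a degree-{degree} fit"
        )
    if len(np.unique(p)) != len(p):
        raise DegenerateDesign("duplicate stage powers")
    design = npoly.polyvander(p, degree)
    coef, res, rank, _ = np.linalg.lstsq(design, c, rcond=None)
    if rank < degree + 1:
        raise DegenerateDesign("rank-deficient polynomial design")
    fitted = design @ coef
    rss = float(np.sum((c - fitted) ** 2))
    return LactateCurve(degree=degree, coefficients=coef,
                        p_min=float(p[0]), p_max=float(p[-1]), rss=rss)


def _real_roots_in(coef: np.ndarray, lo: float, hi: float,
                   open_interval: bool = False) -> np.ndarray:
    """Real roots of an ascending-coefficient polynomial inside [lo, hi]."""
    coef = np.trim_zeros(np.asarray(coef, dtype=float), "b")
    if len(coef) <= 1:
        return np.array([])
    roots = npoly.polyroots(coef)
    roots = roots[np.abs(roots.imag) < 1e-9].real
    tol = 1e-9 * max(1.0, abs(hi))
    if open_interval:
        mask = (roots > lo + tol) & (roots < hi - tol)
    else:
        mask = (roots >= lo - tol) & (roots <= hi + tol)
    return np.sort(np.clip(roots[mask], lo, hi))


def po_at_fixed_lactate(curve: LactateCurve, c_target: float) -> float:
    """Power at which the fitted curve first crosses ``c_target`` rising.

    Returns the smallest root of ``curve(P) = c_target`` inside the
    stage domain at which the curve is locally increasing.
    """
    if c_target <= 0:
        raise ValueError("c_target must be positive")
    shifted = curve.coefficients.copy()
    shifted[0] -= c_target
    deriv = curve.derivative()
    candidates = _real_roots_in(shifted, curve.p_min, curve.p_max)
    increasing = [r for r in candidates if npoly.polyval(r, deriv) > 0]
    if increasing:
        return float(min(increasing))
    if curve(curve.p_min) > c_target:
        raise AlreadyExceeded(
            f"curve already above {c_target} mmol/L at {curve.p_min} W"
        )
    raise NotReached(f"curve never attains {c_target} mmol/L rising in domain")


def po_lt1(test: StepTest) -> float:
    """Last stage power before measured lactate reaches baseline + 1 mmol/L."""
    if len(test.stages) < 2:
        raise InsufficientStages("need at least 2 stages")
    threshold = test.baseline_lactate + 1.0
    for i, stage in enumerate(test.stages):
        if stage.lactate_mmol_l >= threshold:
            if i == 0:
                raise UndeterminedLow(
                    "first stage already >= baseline + 1 mmol/L"
                )
            return float(test.stages[i - 1].power_w)
    raise UndeterminedHigh("no stage reaches baseline + 1 mmol/L")


def po_lt2(curve: LactateCurve) -> Lt2Result:
    """Power of maximal acceleration of a degree-4 lactate curve.

    The second derivative of a quartic is a quadratic; its maximum over
    the domain is at the vertex when concave, else at an endpoint (then
    flagged ``boundary``).
    """
    if curve.degree != 4:
        raise ValueError("po_lt2 requires a degree-4 curve")
    d2 = curve.derivative(2)  # quadratic: d2[0] + d2[1] P + d2[2] P^2
    a2 = d2[2]
    lo, hi = curve.p_min, curve.p_max
    candidates = [lo, hi]
    if a2 < 0:  # concave: interior vertex
        vertex = -d2[1] / (2.0 * a2)
        if lo < vertex < hi:
            candidates.append(vertex)
    values = npoly.polyval(np.array(candidates), d2)
    # ties broken toward lower power
    order = np.lexsort((candidates, -values))
    best = float(candidates[order[0]])
    boundary = best in (lo, hi)
    return Lt2Result(power_w=best, boundary=boundary)


def po_dmax(curve: LactateCurve, test: StepTest) -> float:
    """Power of maximal perpendicular distance from the first/last chord.

    The chord joins the *measured* first and last stage lactates (raw
    axis units, no rescaling).  The maximiser is a root of
    ``curve'(P) = slope`` in the open interval; among stationary points
    the one with the largest perpendicular distance wins, lower power on
    ties.
    """
    p1, pn = test.powers[0], test.powers[-1]
    l1, ln = test.lactates[0], test.lactates[-1]
    if pn <= p1:
        raise DegenerateChord("chord endpoints coincide")
    slope = (ln - l1) / (pn - p1)
    deriv = curve.derivative().copy()
    deriv[0] -= slope
    stationary = _real_roots_in(deriv, p1, pn, open_interval=True)
    if len(stationary) == 0:
        raise DegenerateChord("no interior stationary point of the gap")
    chord = l1 + slope * (stationary - p1)
    gaps = np.abs(np.asarray(curve(stationary)) - chord) / np.hypot(1.0, slope)
    if np.max(gaps) < 1e-6:
        raise DegenerateChord("lactate profile is collinear")
    order = np.lexsort((stationary, -gaps))
    return float(stationary[order[0]])


def extract_thresholds(test: StepTest,
                       fixed_degree: int = 3,
                       lt2_degree: int = 4) -> ThresholdSet:
    """Derive all five markers, degrading per-threshold failures to flags.

    A degree-3 curve serves the fixed-concentration and Dmax markers, a
    degree-4 curve the maximal-acceleration marker (a cubic's second
    derivative is linear and peaks only at a boundary).
    """
    out = ThresholdSet(athlete_id=test.athlete_id)
    try:
        out.po_lt1 = po_lt1(test)
    except Exception as exc:  # noqa: BLE001 - degrade, never abort the athlete
        out.flags["po_lt1"] = type(exc).__name__

    curve3 = None
    try:
        curve3 = fit_lactate_curve(test, degree=fixed_degree)
    except Exception as exc:  # noqa: BLE001
        for name in ("po_x2", "po_x4", "po_dmax"):
            out.flags[name] = type(exc).__name__
    if curve3 is not None:
        for name, target in (("po_x2", 2.0), ("po_x4", 4.0)):
            try:
                setattr(out, name, po_at_fixed_lactate(curve3, target))
            except Exception as exc:  # noqa: BLE001
                out.flags[name] = type(exc).__name__
        try:
            out.po_dmax = po_dmax(curve3, test)
        except Exception as exc:  # noqa: BLE001
            out.flags["po_dmax"] = type(exc).__name__

    try:
        curve4 = fit_lactate_curve(test, degree=lt2_degree)
        result = po_lt2(curve4)
        out.po_lt2 = result.power_w
        if result.boundary:
            out.flags["po_lt2"] = "BoundaryMaximum"
    except Exception as exc:  # noqa: BLE001
        out.flags["po_lt2"] = type(exc).__name__
    return out
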