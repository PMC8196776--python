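"""Published reference values for the studied youth cohort.

These summary statistics (cohort means and SDs of the physiological and
anthropometric profile, the fitted race-time equation and the
literature-comparison power-to-weight entries) parameterise the
synthetic generator defaults and drive the desk-scale worked examples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple


@dataclass(frozen=True)
class Moment:
    mean: float
    sd: float


#: Cohort size of the reference study.
N_ATHLETES = 10

#: Anthropometric profile (absolute units).
ANTHRO_ABSOLUTE: Dict[str, Moment] = {
    "age_yr": Moment(16.3, 0.95),
    "height_cm": Moment(176.74, 4.23),
    "mass_kg": Moment(67.22, 7.49),
    "muscle_kg": Moment(31.89, 5.56),
    "adipose_kg": Moment(15.26, 1.43),
    "bone_kg": Moment(9.11, 1.28),
    "residual_kg": Moment(7.3, 1.17),
    "skin_kg": Moment(3.75, 0.26),
    "sum6_skinfolds_mm": Moment(47.71, 8.24),
}

#: Physiological / strength profile: absolute values (W, cm, N).
MARKERS_ABSOLUTE: Dict[str, Moment] = {
    "po_lt1": Moment(187.0, 28.79),
    "po_lt2": Moment(232.75, 29.54),
    "po_x2": Moment(217.24, 36.93),
    "po_x4": Moment(258.34, 32.4),
    "po_dmax": Moment(228.44, 21.96),
    "po_vo2max": Moment(354.6, 37.81),
    "cp": Moment(262.9, 53.79),
    "p_10min": Moment(286.9, 50.97),
    "p_5min": Moment(319.2, 50.1),
    "p_1min": Moment(499.3, 49.76),
    "p_30s": Moment(704.1, 117.09),
    "p_sprint": Moment(901.6, 178.18),
    "squat_jump_cm": Moment(26.6, 3.72),
    "knee_right_n": Moment(3827.1, 900.3),
    "knee_left_n": Moment(3274.6, 1849.9),
    "knee_asymmetry_n": Moment(493.8, 389.2),
}

#: Physiological profile: body-mass-normalised values (W/kg).
MARKERS_NORMALISED: Dict[str, Moment] = {
    "po_lt1": Moment(2.79, 0.41),
    "po_lt2": Moment(3.48, 0.41),
    "po_x2": Moment(3.24, 0.49),
    "po_x4": Moment(3.86, 0.43),
    "po_dmax": Moment(3.41, 0.29),
    "po_vo2max": Moment(5.29, 0.38),
    "cp": Moment(3.91, 0.65),
    "p_10min": Moment(4.27, 0.58),
    "p_5min": Moment(4.74, 0.51),
    "p_1min": Moment(7.44, 0.26),
    "p_30s": Moment(10.45, 0.94),
    "p_sprint": Moment(13.52, 2.8),
}

#: Published race-time model: minutes = intercept + sum(coef * marker W/kg).
RACE_TIME_INTERCEPT_MIN = 255.86
RACE_TIME_COEFFICIENTS: Dict[str, float] = {
    "po_vo2max": -32.87,
    "po_x4": -51.18,
    "po_x2": 60.77,
}

#: Reported model fit: F(df1, df2) and R^2.
MODEL_F = 7.52
MODEL_DF: Tuple[int, int] = (3, 5)
MODEL_R2 = 0.82

#: Literature-comparison maximal aerobic power in W/kg (rounded, as
#: printed in the comparison table): study label -> (category, value).
COMPARISON_PO_VO2MAX_WKG: Dict[str, Tuple[str, float]] = {
    "impellizzeri_2002": ("elite", 6.4),
    "lee_2002": ("elite", 6.3),
    "stapelfeldt_2004": ("elite", 5.3),
    "impellizzeri_2005a": ("elite", 5.7),
    "baron_2001": ("elite", 5.5),
    "wilber_1997": ("elite", 5.9),
    "fornasiero_2018": ("junior", 6.7),
    "present": ("junior", 5.3),
}


def percent_of(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, ndigits)


def percent_deficit(reference: float, value: float, ndigits: int = 0) -> float:
    """Relative shortfall of ``value`` below ``reference``, in percent."""
    if reference == 0:
        raise ZeroDivisionError("reference must be non-zero")
    out = round(100.0 * (reference - value) / reference, ndigits)
    return out if ndigits > 0 else float(int(out))


def predicted_race_time_min(po_vo2max_wkg: float, po_x4_wkg: float,
                            po_x2_wkg: float) -> float:
    """Evaluate the published race-time equation (minutes)."""
    return (RACE_TIME_INTERCEPT_MIN
            + RACE_TIME_COEFFICIENTS["po_vo2max"] * po_vo2max_wkg
            + RACE_TIME_COEFFICIENTS["po_x4"] * po_x4_wkg
            + RACE_TIME_COEFFICIENTS["po_x2"] * po_x2_wkg)


def r_squared_from_f(f_stat: float, df1: int, df2: int) -> float:
    """Invert F = (R^2/df1) / ((1-R^2)/df2) for R^2."""
    return (df1 * f_stat) / (df1 * f_stat + df2)
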