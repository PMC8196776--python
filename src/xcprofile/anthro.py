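"""Anthropometric indices: skinfold sum, five-way tissue fractionation,
squat-jump height from flight time and isometric strength summaries.

The fractionation follows the phantom z-score scheme: every indicator
measurement is height-corrected to the 170.18 cm phantom stature,
converted to a z-score against the phantom mean/SD, and the mean z of a
tissue's indicators maps back to a tissue mass through the phantom
tissue mass and SD, scaled by (height/170.18)^3.  The phantom constants
ship as a checksummed JSON fixture (see ``data/phantom_constants.json``)
rather than literals in logic.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ConstantsChecksumError, MissingMeasurement

STANDARD_GRAVITY = 9.80665  # m/s^2

PHANTOM_HEIGHT_CM = 170.18

SKINFOLD_SITES = (
    "sf_triceps",
    "sf_subscapular",
    "sf_supraspinale",
    "sf_abdominal",
    "sf_front_thigh",
    "sf_medial_calf",
)

TISSUES = ("adipose", "muscle", "bone", "residual", "skin")


@dataclass
class AnthroMeasures:
    """Raw anthropometric measurement set for one athlete.

    ``measurements`` maps canonical site keys (``sf_*`` skinfolds in mm,
    ``g_*`` girths in cm, ``b_*`` breadths in cm) to values.
    """

    athlete_id: str
    height_cm: float
    mass_kg: float
    measurements: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 100.0 <= self.height_cm <= 220.0:
            raise ValueError("height out of plausible range (100-220 cm)")
        if not 30.0 <= self.mass_kg <= 120.0:
            raise ValueError("mass out of plausible range (30-120 kg)")
        for key, value in self.measurements.items():
            if value < 0:
                raise ValueError(f"measurement {key} must be non-negative")


@dataclass
class FiveWayMasses:
    """Fractionation result; ``None`` mass means undetermined (see flags)."""

    masses_kg: Dict[str, Optional[float]]
    percentages: Dict[str, Optional[float]]
    flags: Dict[str, str] = field(default_factory=dict)

    @property
    def total_kg(self) -> Optional[float]:
        vals = [v for v in self.masses_kg.values() if v is not None]
        return sum(vals) if len(vals) == len(self.masses_kg) else None


@dataclass
class StrengthProfile:
    """Lower-limb strength summary for one athlete."""

    athlete_id: str
    right_max_n: float
    left_max_n: float
    mass_kg: float
    squat_jump_cm: Optional[float] = None

    @property
    def asymmetry_n(self) -> float:
        return abs(self.right_max_n - self.left_max_n)

    @property
    def right_n_per_kg(self) -> float:
        return self.right_max_n / self.mass_kg

    @property
    def left_n_per_kg(self) -> float:
        return self.left_max_n / self.mass_kg


def _canonical_payload(constants: dict) -> str:
    payload = {k: v for k, v in constants.items() if k != "checksum"}
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def load_phantom_constants(path: Optional[str] = None) -> dict:
    """Load and integrity-check the (packaged) fractionation constants."""
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = (resources.files("xcprofile") / "data"
                / "phantom_constants.json").read_text(encoding="utf-8")
    constants = json.loads(text)
    digest = hashlib.sha256(
        _canonical_payload(constants).encode("utf-8")).hexdigest()
    if digest != constants.get("checksum"):
        raise ConstantsChecksumError(
            "phantom constants fixture failed its checksum"
        )
    return constants


def sum6_skinfolds(measures: AnthroMeasures) -> float:
    """Sum of the six standard skinfolds in mm."""
    total = 0.0
    for site in SKINFOLD_SITES:
        if site not in measures.measurements:
            raise MissingMeasurement(f"missing skinfold site: {site}")
        total += measures.measurements[site]
    return total


def five_way_fractionation(measures: AnthroMeasures,
                           constants: Optional[dict] = None) -> FiveWayMasses:
    """Partition body mass into adipose/muscle/bone/residual/skin.

    Per tissue: each indicator x gives z = (x * (170.18/h)^d - p) / s
    with phantom mean p and SD s (d = 1 for all shipped indicators);
    tissue mass = (mean z * S + P) * (h/170.18)^3 with phantom tissue
    mass P and SD S.  Percentages are against measured body mass.
    Missing indicators flag the tissue undetermined instead of aborting.
    """
    if constants is None:
        constants = load_phantom_constants()
    h_ratio = measures.height_cm / PHANTOM_HEIGHT_CM
    meas_consts = constants["measurements"]
    masses: Dict[str, Optional[float]] = {}
    pcts: Dict[str, Optional[float]] = {}
    flags: Dict[str, str] = {}
    for tissue, spec in constants["tissues"].items():
        zs = []
        missing = [k for k in spec["indicators"]
                   if k not in measures.measurements]
        if missing:
            masses[tissue] = None
            pcts[tissue] = None
            flags[tissue] = "missing:" + ",".join(sorted(missing))
            continue
        for key in spec["indicators"]:
            ref = meas_consts[key]
            d = ref.get("dimension", 1)
            x = measures.measurements[key] * (1.0 / h_ratio) ** d
            zs.append((x - ref["mean"]) / ref["sd"])
        z_bar = float(np.mean(zs))
        mass = (z_bar * spec["mass_sd_kg"] + spec["mass_mean_kg"]) * h_ratio ** 3
        if mass <= 0:
            masses[tissue] = None
            pcts[tissue] = None
            flags[tissue] = "nonpositive_mass"
            continue
        masses[tissue] = mass
        pcts[tissue] = 100.0 * mass / measures.mass_kg
    return FiveWayMasses(masses_kg=masses, percentages=pcts, flags=flags)


def jump_height_from_flight(flight_time_s: float) -> float:
    """Squat-jump height (cm) from flight time: h = g t^2 / 8."""
    if not 0.0 < flight_time_s < 1.2:
        raise ValueError("flight time must lie in (0, 1.2) s")
    h_m = STANDARD_GRAVITY * flight_time_s ** 2 / 8.0
    return h_m * 100.0


def flight_time_from_height(height_cm: float) -> float:
    """Inverse of :func:`jump_height_from_flight` (used by the generator)."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    return float(np.sqrt(8.0 * height_cm / 100.0 / STANDARD_GRAVITY))


def isometric_summary(athlete_id: str,
                      right_attempts_n: Sequence[float],
                      left_attempts_n: Sequence[float],
                      mass_kg: float,
                      squat_jump_cm: Optional[float] = None
                      ) -> StrengthProfile:
    """Best-of-attempts knee-extension forces with asymmetry and N/kg."""
    if len(right_attempts_n) == 0 or len(left_attempts_n) == 0:
        raise ValueError("need at least one attempt per leg")
    if mass_kg <= 0:
        raise ValueError("body mass must be positive")
    right = float(max(right_attempts_n))
    left = float(max(left_attempts_n))
    if right <= 0 or left <= 0:
        raise ValueError("forces must be positive")
    return StrengthProfile(athlete_id=athlete_id, right_max_n=right,
                           left_max_n=left, mass_kg=mass_kg,
                           squat_jump_cm=squat_jump_cm)
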