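"""Synthetic athlete cohorts with the statistical structure the analysis
assumes.

The generator draws body-mass-normalised power markers around published
cohort moments with a single shared latent-ability factor (which makes
the markers collinear, as the downstream multicollinearity screen
expects), solves a monotone exponential lactate curve through the exact
2 and 4 mmol/L crossings, and sets the true race time with the published
linear equation plus configurable noise.  Every per-athlete quantity is
drawn from a substream keyed by (seed, athlete index, purpose) so
cohorts are reproducible and extensible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import reference
from .anthro import PHANTOM_HEIGHT_CM, flight_time_from_height, load_phantom_constants
from .errors import ConfigError, UnusableProtocol
from .lactate import Stage, StepTest
from .power import EffortSet, GradedTestEndpoint

# substream purpose codes
_TRUTH, _STEP, _EFFORT, _GRADED, _ANTHRO, _STRENGTH, _RACE = range(7)

#: markers drawn directly from published normalised moments (W/kg)
DRAWN_MARKERS = ("po_x2", "po_x4", "po_vo2max", "cp", "p_1min", "p_30s",
                 "p_sprint")

RACE_LAPS = 4
MIN_RACE_TIME_MIN = 30.0

COHORT_FILES = ("athletes.csv", "lactate_tests.csv", "power_efforts.csv",
                "graded_test.csv", "anthropometry.csv", "strength.csv",
                "race.csv", "truth.csv")

_EFFORT_NAME = {"p_sprint": "sprint6s", "p_30s": "p30s", "p_1min": "p1min",
                "p_5min": "p5min", "p_10min": "p10min"}


def _default_means() -> Dict[str, float]:
    return {k: reference.MARKERS_NORMALISED[k].mean for k in DRAWN_MARKERS}


def _default_sds() -> Dict[str, float]:
    return {k: reference.MARKERS_NORMALISED[k].sd for k in DRAWN_MARKERS}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator (all noise SDs >= 0)."""

    n_athletes: int = 10
    seed: int = 0
    marker_means: Dict[str, float] = field(default_factory=_default_means)
    marker_sds: Dict[str, float] = field(default_factory=_default_sds)
    mass_mean_kg: float = 67.22
    mass_sd_kg: float = 7.49
    latent_correlation: float = 0.85
    race_noise_sd_min: float = 2.0
    stage_lactate_noise_sd: float = 0.15
    effort_power_noise_cv: float = 0.02
    baseline_lactate_mean: float = 1.0
    baseline_lactate_sd: float = 0.2
    drop_one_athlete: bool = False  # mimic one incomplete case
    emit_streams: bool = False

    def __post_init__(self) -> None:
        if self.n_athletes < 1:
            raise ConfigError("n_athletes must be >= 1")
        if not 0.0 <= self.latent_correlation < 1.0:
            raise ConfigError("latent correlation must lie in [0, 1)")
        for name in ("mass_sd_kg", "race_noise_sd_min",
                     "stage_lactate_noise_sd", "effort_power_noise_cv",
                     "baseline_lactate_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if set(self.marker_means) != set(DRAWN_MARKERS) \
                or set(self.marker_sds) != set(DRAWN_MARKERS):
            raise ConfigError(
                f"marker_means/marker_sds must cover exactly {DRAWN_MARKERS}"
            )
        if any(v < 0 for v in self.marker_sds.values()):
            raise ConfigError("marker SDs must be >= 0")


@dataclass
class TrueAthleteState:
    """Latent truth for one synthetic athlete."""

    athlete_id: str
    mass_kg: float
    latent_ability: float
    markers_wkg: Dict[str, float]  # drawn normalised markers
    baseline_lactate: float
    lactate_a: float
    lactate_k: float
    race_time_min: float
    age_yr: float
    height_cm: float

    @property
    def w_prime_j(self) -> float:
        return 60.0 * (self.markers_wkg["p_1min"]
                       - self.markers_wkg["cp"]) * self.mass_kg

    def marker_w(self, name: str) -> float:
        return self.markers_wkg[name] * self.mass_kg

    def lactate_at(self, power_w: float) -> float:
        """Noiseless lactate concentration c(P) = c_b + a * exp(k P)."""
        return self.baseline_lactate + self.lactate_a * math.exp(
            self.lactate_k * power_w)

    def po_at_lactate(self, c_target: float) -> float:
        """Exact inverse of the generative lactate curve."""
        if c_target <= self.baseline_lactate:
            raise ValueError("target below baseline is never attained")
        return math.log((c_target - self.baseline_lactate) / self.lactate_a
                        ) / self.lactate_k


@dataclass
class SimulatedCohort:
    """Full simulated data bundle for one cohort."""

    config: GeneratorConfig
    truth: List[TrueAthleteState]
    step_tests: List[StepTest]
    efforts: List[EffortSet]
    graded: List[GradedTestEndpoint]
    anthropometry: pd.DataFrame
    strength: pd.DataFrame
    race: pd.DataFrame
    streams: Optional[pd.DataFrame] = None


def _substream(config: GeneratorConfig, athlete: int, purpose: int
               ) -> np.random.Generator:
    return np.random.default_rng([config.seed, athlete, purpose])


def _draw_athlete_truth(config: GeneratorConfig, index: int
                        ) -> TrueAthleteState:
    rng = _substream(config, index, _TRUTH)
    r = config.latent_correlation
    for _ in range(1000):
        ability = rng.standard_normal()
        eps = rng.standard_normal(len(DRAWN_MARKERS))
        markers = {
            name: config.marker_means[name] + config.marker_sds[name]
            * (math.sqrt(r) * ability + math.sqrt(1.0 - r) * eps[j])
            for j, name in enumerate(DRAWN_MARKERS)
        }
        mass = config.mass_mean_kg + config.mass_sd_kg * rng.standard_normal()
        baseline = (config.baseline_lactate_mean
                    + config.baseline_lactate_sd * rng.standard_normal())
        height = 176.74 + 4.23 * rng.standard_normal()
        age = float(np.clip(16.3 + 0.95 * rng.standard_normal(), 14.0, 18.0))
        if mass <= 0 or not 110.0 <= height <= 215.0:
            continue
        if not 0.4 <= baseline <= 1.7:
            continue
        if not (0 < markers["po_x2"] < markers["po_x4"]
                < markers["po_vo2max"]):
            continue  # impossible lactate solve or unordered truth: redraw
        if markers["po_x4"] * mass <= 150.0:
            continue  # athlete below the 150 W protocol floor: redraw
        if (markers["po_x4"] - markers["po_x2"]) * mass < 5.0:
            continue  # degenerate 2-4 mmol/L spread (curve blows up): redraw
        if markers["cp"] <= 0 or markers["p_1min"] <= markers["cp"]:
            continue
        po_x2_w = markers["po_x2"] * mass
        po_x4_w = markers["po_x4"] * mass
        k = math.log((4.0 - baseline) / (2.0 - baseline)) / (po_x4_w - po_x2_w)
        a = (2.0 - baseline) * math.exp(-k * po_x2_w)
        noise = (config.race_noise_sd_min * rng.standard_normal()
                 if config.race_noise_sd_min > 0 else 0.0)
        race = reference.predicted_race_time_min(
            markers["po_vo2max"], markers["po_x4"], markers["po_x2"]) + noise
        race = max(race, MIN_RACE_TIME_MIN)
        return TrueAthleteState(
            athlete_id=f"A{index + 1:03d}", mass_kg=float(mass),
            latent_ability=float(ability), markers_wkg=markers,
            baseline_lactate=float(baseline), lactate_a=a, lactate_k=k,
            race_time_min=float(race), age_yr=age, height_cm=float(height),
        )
    raise ConfigError("could not draw a physiologically valid athlete "
                      "(configuration too extreme)")


def sample_cohort_truth(config: GeneratorConfig) -> List[TrueAthleteState]:
    """Draw the latent truth for every athlete in the cohort."""
    return [_draw_athlete_truth(config, i) for i in range(config.n_athletes)]


def simulate_step_test(state: TrueAthleteState, noise_sd: float,
                       start_w: float = 150.0, increment_w: float = 25.0,
                       rng: Optional[np.random.Generator] = None) -> StepTest:
    """Simulate the 25 W / 5 min lactate step test for one athlete.

    Stages run from ``start_w`` upward and stop at (and include) the
    first stage whose *noiseless* lactate exceeds 4 mmol/L, which keeps
    stage counts identical across noise settings.  Measured values add
    Normal(0, noise_sd) noise, clipped at 0.4 mmol/L.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if state.lactate_at(start_w) > 4.0:
        raise UnusableProtocol(
            f"first stage at {start_w} W already beyond the 4 mmol/L stop rule"
        )
    powers = [start_w]
    while state.lactate_at(powers[-1]) <= 4.0:
        powers.append(powers[-1] + increment_w)
    n = len(powers)
    noise = rng.normal(0.0, noise_sd, size=n + 1) if noise_sd > 0 \
        else np.zeros(n + 1)
    baseline = max(state.baseline_lactate + noise[0], 0.4)
    top = powers[-1]
    stages = []
    for i, p in enumerate(powers):
        lac = max(state.lactate_at(p) + noise[i + 1], 0.4)
        frac = (p - start_w) / max(top - start_w, increment_w)
        hr = round(125.0 + 65.0 * frac)
        rpe = round(min(3.0 + 6.0 * frac, 10.0), 1)
        stages.append(Stage(power_w=float(p), lactate_mmol_l=float(lac),
                            hr_bpm=float(hr), rpe=float(rpe)))
    return StepTest(athlete_id=state.athlete_id,
                    baseline_lactate=float(baseline), stages=stages)


def simulate_power_profile(state: TrueAthleteState, config: GeneratorConfig,
                           rng: Optional[np.random.Generator] = None
                           ) -> EffortSet:
    """Per-effort mean powers from the athlete's CP/W' truth and markers.

    The 1, 5 and 10 min efforts follow P = CP + W'/t; the 6 s and 30 s
    efforts come from the drawn sprint markers.  All efforts carry
    multiplicative Normal(1, cv) noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cp_w = state.marker_w("cp")
    wp = state.w_prime_j
    cv = config.effort_power_noise_cv
    means = {
        "p_sprint": state.marker_w("p_sprint"),
        "p_30s": state.marker_w("p_30s"),
        "p_1min": cp_w + wp / 60.0,
        "p_5min": cp_w + wp / 300.0,
        "p_10min": cp_w + wp / 600.0,
    }
    factors = rng.normal(1.0, cv, size=len(means)) if cv > 0 \
        else np.ones(len(means))
    noisy = {k: max(v * f, 1.0)
             for (k, v), f in zip(means.items(), factors)}
    return EffortSet(athlete_id=state.athlete_id,
                     sprint6s=noisy["p_sprint"], p30s=noisy["p_30s"],
                     p1min=noisy["p_1min"], p5min=noisy["p_5min"],
                     p10min=noisy["p_10min"])


def simulate_power_stream(mean_power_w: float, duration_s: int,
                          noise_sd: float,
                          rng: Optional[np.random.Generator] = None
                          ) -> np.ndarray:
    """Constant-power 1 Hz stream with white noise, mean kept exact."""
    if rng is None:
        rng = np.random.default_rng(0)
    noise = rng.normal(0.0, noise_sd, size=duration_s)
    noise -= noise.mean()  # keep window mean equal to the effort mean
    return mean_power_w + noise


def simulate_graded_endpoint(state: TrueAthleteState,
                             rng: Optional[np.random.Generator] = None
                             ) -> GradedTestEndpoint:
    """Graded-test endpoint whose end-test power equals the true maximum.

    The last completed workload is the largest 25 W grid point not above
    the truth; the seconds into the uncompleted stage carry the
    remainder, so the end-test equation recovers the truth exactly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    vo2_w = state.marker_w("po_vo2max")
    w_f = 25.0 * math.floor(vo2_w / 25.0)
    t = (vo2_w - w_f) / 25.0 * 60.0
    hr_max = (220.0 - state.age_yr) * rng.uniform(0.86, 0.97)
    return GradedTestEndpoint(
        athlete_id=state.athlete_id, last_completed_w=w_f,
        seconds_into_stage=float(t), max_rpe=10.0,
        max_hr_bpm=float(round(hr_max)), age_yr=state.age_yr,
    )


def _simulate_anthro_row(state: TrueAthleteState, constants: dict,
                         rng: np.random.Generator) -> Dict[str, float]:
    """Measurement set consistent with the athlete's stature and mass.

    Skinfolds are phantom-proportioned but rescaled so the six-site sum
    lands around the published cohort mean; girths and breadths share a
    single multiplier solved (linearly, via the phantom z-score model)
    so the five-way tissue masses sum to the athlete's body mass before
    per-site measurement noise.
    """
    meas = constants["measurements"]
    tissues = constants["tissues"]
    h_ratio = state.height_cm / PHANTOM_HEIGHT_CM
    sum6_target = float(np.clip(rng.normal(47.71, 8.24), 22.0, 90.0))
    sf_keys = tissues["adipose"]["indicators"]
    phantom_sum6 = sum(meas[k]["mean"] for k in sf_keys)
    sf_scale = sum6_target / phantom_sum6

    # adipose mass implied by the skinfold scale
    kappa_a = float(np.mean([meas[k]["mean"] / meas[k]["sd"]
                             for k in sf_keys]))
    adipose = ((sf_scale - 1.0) * kappa_a * tissues["adipose"]["mass_sd_kg"]
               + tissues["adipose"]["mass_mean_kg"]) * h_ratio ** 3

    # one girth/breadth multiplier g so that the tissue masses sum to
    # body mass: sum_others(g) = h^3 * (S0 + (g-1) * K) with
    # K = sum_t mean_i(p_i/s_i) * S_t over the non-adipose tissues
    s0 = 0.0
    k_total = 0.0
    for name, spec in tissues.items():
        if name == "adipose":
            continue
        s0 += spec["mass_mean_kg"]
        kappa = float(np.mean([meas[k]["mean"] / meas[k]["sd"]
                               for k in spec["indicators"]]))
        k_total += kappa * spec["mass_sd_kg"]
    target_others = state.mass_kg - adipose
    g = 1.0 + (target_others / h_ratio ** 3 - s0) / k_total
    g = float(np.clip(g, 0.75, 1.3))

    row: Dict[str, float] = {"athlete_id": state.athlete_id,
                             "height_cm": round(state.height_cm, 2),
                             "mass_kg": round(state.mass_kg, 2)}
    for key, ref in meas.items():
        if key.startswith("sf_"):
            value = ref["mean"] * sf_scale * h_ratio * rng.normal(1.0, 0.04)
        else:
            value = ref["mean"] * g * h_ratio * rng.normal(1.0, 0.01)
        row[key] = round(max(value, 0.5), 2)
    return row


def _simulate_strength_rows(state: TrueAthleteState,
                            rng: np.random.Generator) -> List[Dict]:
    sj_cm = float(np.clip(rng.normal(26.6, 3.72), 8.0, 60.0))
    best_flight = flight_time_from_height(sj_cm)
    right = float(np.clip(rng.normal(3827.1, 900.3), 800.0, 8000.0))
    left = float(np.clip(rng.normal(3274.6, 1849.9), 800.0, 8000.0))
    rows = []
    for attempt in range(1, 4):
        sub = rng.uniform(0.90, 1.0, size=3)
        rows.append({"athlete_id": state.athlete_id, "test": "sj_flight_s",
                     "attempt": attempt,
                     "value": round(best_flight * (1.0 if attempt == 3
                                                   else sub[0]), 4)})
        rows.append({"athlete_id": state.athlete_id, "test": "knee_right_n",
                     "attempt": attempt,
                     "value": round(right * (1.0 if attempt == 2
                                             else sub[1]), 1)})
        rows.append({"athlete_id": state.athlete_id, "test": "knee_left_n",
                     "attempt": attempt,
                     "value": round(left * (1.0 if attempt == 3
                                            else sub[2]), 1)})
    return rows


def _simulate_race_rows(state: TrueAthleteState,
                        rng: np.random.Generator) -> List[Dict]:
    total_s = state.race_time_min * 60.0
    frac = np.clip(0.25 + rng.normal(0.0, 0.015, size=RACE_LAPS), 0.15, 0.35)
    frac = frac / frac.sum()
    return [{"athlete_id": state.athlete_id, "lap_index": lap + 1,
             "lap_time_s": round(float(total_s * frac[lap]), 2)}
            for lap in range(RACE_LAPS)]


def generate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Simulate every test battery for a full cohort."""
    truth = sample_cohort_truth(config)
    constants = load_phantom_constants()
    step_tests, efforts, graded = [], [], []
    anthro_rows, strength_rows, race_rows, stream_rows = [], [], [], []
    for i, state in enumerate(truth):
        step_tests.append(simulate_step_test(
            state, config.stage_lactate_noise_sd,
            rng=_substream(config, i, _STEP)))
        effort_rng = _substream(config, i, _EFFORT)
        effort = simulate_power_profile(state, config, rng=effort_rng)
        efforts.append(effort)
        graded.append(simulate_graded_endpoint(
            state, rng=_substream(config, i, _GRADED)))
        anthro_rows.append(_simulate_anthro_row(
            state, constants, _substream(config, i, _ANTHRO)))
        strength_rows.extend(_simulate_strength_rows(
            state, _substream(config, i, _STRENGTH)))
        race_rows.extend(_simulate_race_rows(
            state, _substream(config, i, _RACE)))
        if config.emit_streams:
            for name, dur in (("p1min", 60), ("p5min", 300), ("p10min", 600)):
                stream = simulate_power_stream(
                    getattr(effort, name), dur, 5.0, rng=effort_rng)
                stream_rows.extend(
                    {"athlete_id": state.athlete_id, "effort": name,
                     "t_s": t, "power_w": round(float(v), 3)}
                    for t, v in enumerate(stream))
    race = pd.DataFrame(race_rows)
    if config.drop_one_athlete and config.n_athletes >= 2:
        # mimic one incomplete case: drop one athlete's race result
        drop_rng = np.random.default_rng([config.seed, config.n_athletes,
                                          _RACE + 1])
        dropped = truth[int(drop_rng.integers(config.n_athletes))].athlete_id
        race = race[race["athlete_id"] != dropped].reset_index(drop=True)
    race_rows = race.to_dict("records")
    streams = pd.DataFrame(stream_rows) if config.emit_streams else None
    return SimulatedCohort(
        config=config, truth=truth, step_tests=step_tests, efforts=efforts,
        graded=graded, anthropometry=pd.DataFrame(anthro_rows),
        strength=pd.DataFrame(strength_rows), race=pd.DataFrame(race_rows),
        streams=streams,
    )


def _truth_frame(truth: List[TrueAthleteState]) -> pd.DataFrame:
    rows = []
    for s in truth:
        row = {"athlete_id": s.athlete_id, "mass_kg": s.mass_kg,
               "height_cm": s.height_cm, "age_yr": s.age_yr,
               "latent_ability": s.latent_ability,
               "baseline_lactate_mmol_l": s.baseline_lactate,
               "lactate_a": s.lactate_a, "lactate_k": s.lactate_k,
               "w_prime_j": s.w_prime_j, "race_time_min": s.race_time_min}
        for name, value in s.markers_wkg.items():
            row[f"{name}_wkg"] = value
            row[f"{name}_w"] = value * s.mass_kg
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(directory: str | Path, cohort: SimulatedCohort) -> Path:
    """Write the cohort as the fixed CSV file contract; returns the dir."""
    out = Path(directory)
    if not out.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out}")
    athletes = pd.DataFrame(
        {"athlete_id": [s.athlete_id for s in cohort.truth],
         "age_yr": [round(s.age_yr, 1) for s in cohort.truth],
         "height_cm": [round(s.height_cm, 2) for s in cohort.truth],
         "mass_kg": [round(s.mass_kg, 2) for s in cohort.truth],
         "baseline_lactate_mmol_l": [round(t.baseline_lactate, 3)
                                     for t in cohort.step_tests]})
    athletes.to_csv(out / "athletes.csv", index=False)

    lact_rows = []
    for test in cohort.step_tests:
        for j, stage in enumerate(test.stages):
            lact_rows.append({"athlete_id": test.athlete_id, "stage_index": j,
                              "stage_power_w": stage.power_w,
                              "lactate_mmol_l": round(stage.lactate_mmol_l, 3),
                              "hr_bpm": stage.hr_bpm, "rpe_1_10": stage.rpe})
    pd.DataFrame(lact_rows).to_csv(out / "lactate_tests.csv", index=False)

    effort_rows = []
    for eff in cohort.efforts:
        for marker, name in _EFFORT_NAME.items():
            value = getattr(eff, name)
            if value is not None:
                effort_rows.append({"athlete_id": eff.athlete_id,
                                    "effort": name,
                                    "mean_power_w": round(value, 3)})
    pd.DataFrame(effort_rows).to_csv(out / "power_efforts.csv", index=False)

    graded = pd.DataFrame(
        [{"athlete_id": g.athlete_id, "last_completed_w": g.last_completed_w,
          "seconds_into_stage": round(g.seconds_into_stage, 3),
          "max_rpe_1_10": g.max_rpe, "max_hr_bpm": g.max_hr_bpm}
         for g in cohort.graded])
    graded.to_csv(out / "graded_test.csv", index=False)

    cohort.anthropometry.to_csv(out / "anthropometry.csv", index=False)
    cohort.strength.to_csv(out / "strength.csv", index=False)
    cohort.race.to_csv(out / "race.csv", index=False)
    _truth_frame(cohort.truth).to_csv(out / "truth.csv", index=False)
    if cohort.streams is not None:
        cohort.streams.to_csv(out / "power_streams.csv", index=False)
    return out


def read_cohort(directory: str | Path) -> Dict[str, pd.DataFrame]:
    """Read the cohort CSV contract back into dataframes."""
    out = {}
    for name in COHORT_FILES:
        path = Path(directory) / name
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
        out[name.removesuffix(".csv")] = pd.read_csv(path)
    return out
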