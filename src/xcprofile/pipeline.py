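"""Orchestration: simulate -> markers -> analyze -> report.

File contracts are the cohort CSV schemas defined in :mod:`cohort`, a
per-athlete ``markers.csv`` (absolute W and W/kg columns plus flags) and
a ``report.json`` carrying the correlation screen, VIF table, stepwise
traces, final model and per-athlete predictions with provenance.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .anthro import (
    AnthroMeasures,
    five_way_fractionation,
    isometric_summary,
    jump_height_from_flight,
    load_phantom_constants,
    sum6_skinfolds,
)
from .cohort import GeneratorConfig, SimulatedCohort, generate_cohort, write_cohort
from .errors import ConfigError
from .lactate import Stage, StepTest, extract_thresholds
from .power import CP_DURATIONS_S, GradedTestEndpoint, check_test_validity, fit_cp, kuipers_po_vo2max
from .stats import RegressionReport, analyze_markers, shapiro_wilk_screen

#: W/kg candidate predictors offered to the correlation screen.
CANDIDATE_MARKERS = ("po_lt1", "po_lt2", "po_x2", "po_x4", "po_dmax",
                     "po_vo2max", "cp", "p_sprint", "p_30s", "p_1min",
                     "p_5min", "p_10min")

_EFFORT_TO_MARKER = {"sprint6s": "p_sprint", "p30s": "p_30s",
                     "p1min": "p_1min", "p5min": "p_5min",
                     "p10min": "p_10min"}


@dataclass
class PipelineConfig:
    """Tunable analysis knobs with the study's defaults."""

    alpha_screen: float = 0.05
    vif_threshold: float = 5.0
    alpha_stay: float = 0.05
    alpha_enter: float = 0.05
    n_boot: int = 10_000
    seed: int = 0
    fixed_curve_degree: int = 3
    lt2_curve_degree: int = 4
    cp_durations_s: tuple = CP_DURATIONS_S
    normalise_to_mass: bool = True
    min_cases: int = 6

    def __post_init__(self) -> None:
        for name in ("alpha_screen", "alpha_stay", "alpha_enter"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.vif_threshold <= 1.0:
            raise ConfigError("vif_threshold must exceed 1")
        if self.fixed_curve_degree not in (3, 4) \
                or self.lt2_curve_degree not in (3, 4):
            raise ConfigError("curve degrees must be 3 or 4")
        if len(set(self.cp_durations_s)) != len(self.cp_durations_s):
            raise ConfigError("cp durations must be distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cp_durations_s" in raw:
            raw["cp_durations_s"] = tuple(raw["cp_durations_s"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_simulate(out_dir: str | Path, generator_config: GeneratorConfig,
                 force: bool = False) -> SimulatedCohort:
    """Generate a cohort and write the CSV contract plus a manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigError(
            f"output directory {out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(generator_config)
    write_cohort(out, cohort)
    manifest = {
        "tool": "xcprofile",
        "version": __version__,
        "seed": generator_config.seed,
        "generator_config": dataclasses.asdict(generator_config),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return cohort


def _step_tests_from_tables(lactate: pd.DataFrame, athletes: pd.DataFrame
                            ) -> Dict[str, StepTest]:
    baselines = athletes.set_index("athlete_id")[
        "baseline_lactate_mmol_l"].to_dict()
    tests = {}
    for athlete_id, grp in lactate.groupby("athlete_id", sort=False):
        grp = grp.sort_values("stage_index")
        stages = [Stage(power_w=row.stage_power_w,
                        lactate_mmol_l=row.lactate_mmol_l,
                        hr_bpm=getattr(row, "hr_bpm", None),
                        rpe=getattr(row, "rpe_1_10", None))
                  for row in grp.itertuples()]
        tests[athlete_id] = StepTest(athlete_id=athlete_id,
                                     baseline_lactate=baselines[athlete_id],
                                     stages=stages)
    return tests


def _anthro_from_row(row: pd.Series) -> AnthroMeasures:
    skip = {"athlete_id", "height_cm", "mass_kg"}
    measurements = {k: float(v) for k, v in row.items()
                    if k not in skip and pd.notna(v)}
    return AnthroMeasures(athlete_id=row["athlete_id"],
                          height_cm=float(row["height_cm"]),
                          mass_kg=float(row["mass_kg"]),
                          measurements=measurements)


def run_markers(cohort_dir: str | Path, config: Optional[PipelineConfig] = None
                ) -> pd.DataFrame:
    """Derive all per-athlete markers from the cohort CSVs.

    Writes ``markers.csv``, ``thresholds.csv``, ``body_comp.csv`` and
    ``strength_summary.csv`` into the cohort directory and returns the
    marker table.  Per-athlete failures degrade to flags; athletes are
    never dropped.
    """
    config = config or PipelineConfig()
    src = Path(cohort_dir)
    needed = ["athletes.csv", "lactate_tests.csv", "power_efforts.csv",
              "graded_test.csv", "anthropometry.csv", "strength.csv"]
    for name in needed:
        if not (src / name).exists():
            raise FileNotFoundError(f"missing input file: {src / name}")
    athletes = pd.read_csv(src / "athletes.csv")
    lactate = pd.read_csv(src / "lactate_tests.csv")
    efforts = pd.read_csv(src / "power_efforts.csv")
    graded = pd.read_csv(src / "graded_test.csv")
    anthro = pd.read_csv(src / "anthropometry.csv")
    strength = pd.read_csv(src / "strength.csv")

    step_tests = _step_tests_from_tables(lactate, athletes)
    constants = load_phantom_constants()

    marker_rows, threshold_rows, body_rows, strength_rows = [], [], [], []
    for athlete in athletes.itertuples():
        aid = athlete.athlete_id
        flags: List[str] = []
        row: Dict[str, object] = {"athlete_id": aid,
                                  "mass_kg": athlete.mass_kg}

        # lactate thresholds
        if aid in step_tests:
            tset = extract_thresholds(step_tests[aid],
                                      fixed_degree=config.fixed_curve_degree,
                                      lt2_degree=config.lt2_curve_degree)
            tdict = tset.as_dict()
            threshold_rows.append({"athlete_id": aid, **tdict})
            for key in ("po_lt1_w", "po_lt2_w", "po_x2_w", "po_x4_w",
                        "po_dmax_w"):
                row[key] = tdict[key]
            if tdict["flags"]:
                flags.append(tdict["flags"])
        else:
            flags.append("no_step_test")

        # power profile
        eff_grp = efforts[efforts["athlete_id"] == aid]
        eff_map = dict(zip(eff_grp["effort"], eff_grp["mean_power_w"]))
        for effort, marker in _EFFORT_TO_MARKER.items():
            row[f"{marker}_w"] = eff_map.get(effort)
        cp_pts = [(t, eff_map[name]) for t, name in
                  zip(config.cp_durations_s, ("p1min", "p5min", "p10min"))
                  if name in eff_map]
        try:
            model = fit_cp(cp_pts)
            row["cp_w"] = model.cp_w
            row["w_prime_kj"] = model.w_prime_kj
            row["cp_r_squared"] = model.r_squared
        except Exception as exc:  # noqa: BLE001
            flags.append(f"cp:{type(exc).__name__}")
            row["cp_w"] = None
            row["w_prime_kj"] = None

        # graded maximal test
        grd = graded[graded["athlete_id"] == aid]
        if len(grd):
            g = grd.iloc[0]
            endpoint = GradedTestEndpoint(
                athlete_id=aid,
                last_completed_w=float(g["last_completed_w"]),
                seconds_into_stage=float(g["seconds_into_stage"]),
                max_rpe=float(g["max_rpe_1_10"])
                if "max_rpe_1_10" in g and pd.notna(g["max_rpe_1_10"]) else None,
                max_hr_bpm=float(g["max_hr_bpm"])
                if "max_hr_bpm" in g and pd.notna(g["max_hr_bpm"]) else None,
                age_yr=float(athlete.age_yr),
            )
            row["po_vo2max_w"] = kuipers_po_vo2max(endpoint)
            row["validity_flag"] = check_test_validity(endpoint)
            if row["validity_flag"] == "invalid":
                flags.append("graded_test_invalid")
        else:
            flags.append("no_graded_test")
            row["po_vo2max_w"] = None
            row["validity_flag"] = "unknown"

        # normalise to body mass
        if config.normalise_to_mass:
            for name in CANDIDATE_MARKERS:
                watts = row.get(f"{name}_w")
                row[f"{name}_wkg"] = (None if watts is None or pd.isna(watts)
                                      else float(watts) / athlete.mass_kg)

        # anthropometry + strength
        arow = anthro[anthro["athlete_id"] == aid]
        if len(arow):
            measures = _anthro_from_row(arow.iloc[0])
            body = {"athlete_id": aid}
            try:
                body["sum6_skinfolds_mm"] = sum6_skinfolds(measures)
            except Exception as exc:  # noqa: BLE001
                flags.append(f"sum6:{type(exc).__name__}")
            frac = five_way_fractionation(measures, constants)
            for tissue, mass in frac.masses_kg.items():
                body[f"{tissue}_kg"] = mass
                body[f"{tissue}_pct"] = frac.percentages[tissue]
            if frac.flags:
                flags.append("fractionation:" + ",".join(sorted(frac.flags)))
            total = frac.total_kg
            if total is not None and abs(total - measures.mass_kg) \
                    > 0.08 * measures.mass_kg:
                flags.append("fractionation_sum_off_tolerance")
            body_rows.append(body)
        else:
            flags.append("no_anthropometry")

        sgrp = strength[strength["athlete_id"] == aid]
        if len(sgrp):
            try:
                flights = sgrp[sgrp["test"] == "sj_flight_s"]["value"]
                sj_cm = (jump_height_from_flight(float(flights.max()))
                         if len(flights) else None)
                profile = isometric_summary(
                    aid,
                    sgrp[sgrp["test"] == "knee_right_n"]["value"].tolist(),
                    sgrp[sgrp["test"] == "knee_left_n"]["value"].tolist(),
                    mass_kg=float(athlete.mass_kg), squat_jump_cm=sj_cm)
                strength_rows.append({
                    "athlete_id": aid,
                    "squat_jump_cm": profile.squat_jump_cm,
                    "knee_right_n": profile.right_max_n,
                    "knee_left_n": profile.left_max_n,
                    "knee_asymmetry_n": profile.asymmetry_n,
                    "knee_right_n_kg": profile.right_n_per_kg,
                    "knee_left_n_kg": profile.left_n_per_kg,
                })
            except Exception as exc:  # noqa: BLE001
                flags.append(f"strength:{type(exc).__name__}")
        else:
            flags.append("no_strength_data")

        row["flags"] = ";".join(flags)
        marker_rows.append(row)

    markers = pd.DataFrame(marker_rows)
    markers.to_csv(src / "markers.csv", index=False)
    pd.DataFrame(threshold_rows).to_csv(src / "thresholds.csv", index=False)
    pd.DataFrame(body_rows).to_csv(src / "body_comp.csv", index=False)
    pd.DataFrame(strength_rows).to_csv(src / "strength_summary.csv",
                                       index=False)
    return markers


def total_race_time_min(race: pd.DataFrame) -> pd.DataFrame:
    """Sum lap times per athlete into total race time (minutes)."""
    total = race.groupby("athlete_id", sort=False)["lap_time_s"].sum() / 60.0
    return total.rename("race_time_min").reset_index()


def marker_matrix(markers: pd.DataFrame, race: pd.DataFrame) -> pd.DataFrame:
    """Join W/kg candidate columns with the race outcome, one row/athlete."""
    cols = ["athlete_id"] + [f"{m}_wkg" for m in CANDIDATE_MARKERS
                             if f"{m}_wkg" in markers.columns]
    frame = markers[cols].merge(total_race_time_min(race), on="athlete_id",
                                how="left")
    frame = frame.rename(columns={f"{m}_wkg": m for m in CANDIDATE_MARKERS})
    return frame


def truth_marker_matrix(truth: pd.DataFrame, race: pd.DataFrame
                        ) -> pd.DataFrame:
    """Marker matrix built from the generator truth table (noise-free)."""
    cols = {c: c.removesuffix("_wkg") for c in truth.columns
            if c.endswith("_wkg")}
    frame = truth[["athlete_id", *cols]].rename(columns=cols)
    return frame.merge(total_race_time_min(race), on="athlete_id",
                       how="left")


def _correlations_payload(report: RegressionReport) -> List[dict]:
    return [{"variable": c.variable, "rho": c.rho, "p_value": c.p_value,
             "ci95": list(c.ci95) if c.ci95 else None, "n": c.n,
             "p_method": c.p_method, "ci_method": c.ci_method,
             "retained": c.retained, "flag": c.flag}
            for c in report.correlations]


def run_analyze(cohort_dir: str | Path,
                config: Optional[PipelineConfig] = None,
                markers_source: str = "estimated") -> dict:
    """Correlation screen and stepwise regression on a cohort directory.

    ``markers_source="estimated"`` uses ``markers.csv`` (computing it if
    absent); ``"truth"`` uses the generator truth table, which is the
    noise-free route used for parameter-recovery checks.  Writes
    ``report.json`` and flat ``report.csv`` tables; returns the report
    payload.
    """
    config = config or PipelineConfig()
    src = Path(cohort_dir)
    race_path = src / "race.csv"
    if not race_path.exists():
        raise FileNotFoundError(f"missing input file: {race_path}")
    race = pd.read_csv(race_path)
    if markers_source == "truth":
        frame = truth_marker_matrix(pd.read_csv(src / "truth.csv"), race)
    elif markers_source == "estimated":
        markers_path = src / "markers.csv"
        markers = (pd.read_csv(markers_path) if markers_path.exists()
                   else run_markers(src, config))
        frame = marker_matrix(markers, race)
    else:
        raise ConfigError("markers_source must be 'estimated' or 'truth'")

    analysis_frame = frame.drop(columns=["athlete_id"])
    report = analyze_markers(
        analysis_frame, outcome="race_time_min",
        alpha_screen=config.alpha_screen, vif_threshold=config.vif_threshold,
        alpha_stay=config.alpha_stay, alpha_enter=config.alpha_enter,
        n_boot=config.n_boot, seed=config.seed, min_cases=config.min_cases)

    complete = frame.dropna()
    normality = shapiro_wilk_screen(
        complete.drop(columns=["athlete_id"]))
    predictions = report.predictions.copy()
    predictions.insert(0, "athlete_id", complete["athlete_id"].to_numpy())

    payload = {
        "provenance": {"tool": "xcprofile", "version": __version__,
                       "seed": config.seed, "config_digest": config.digest(),
                       "markers_source": markers_source},
        "n_input_athletes": int(frame["athlete_id"].nunique()),
        "n_analysed": int(len(complete)),
        "normality": normality.to_dict("records"),
        "correlations": _correlations_payload(report),
        "vif_table": report.vif_table,
        "backward_trace": report.backward_trace,
        "forward_trace": report.forward_trace,
        "model": {
            "intercept": report.intercept,
            "coefficients": report.coefficients,
            "r_squared": report.r_squared,
            "f_stat": report.f_stat,
            "df": list(report.df),
            "p_value": report.p_value,
            "n": report.n,
        },
        "predictions": predictions.to_dict("records"),
        "warnings": report.warnings,
    }
    (src / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n",
        encoding="utf-8")
    pd.DataFrame(payload["correlations"]).to_csv(src / "report.csv",
                                                 index=False)
    return payload


def format_report(payload: dict) -> str:
    """Human-readable summary of a ``report.json`` payload."""
    lines = ["xcprofile analysis report",
             f"  athletes analysed: {payload['n_analysed']} "
             f"of {payload['n_input_athletes']}"]
    retained = [c for c in payload["correlations"] if c["retained"]]
    lines.append(f"  screened-in predictors (p < alpha): "
                 f"{', '.join(c['variable'] for c in retained) or 'none'}")
    model = payload["model"]
    terms = " ".join(f"{b:+.2f}*{k}" for k, b in model["coefficients"].items())
    lines.append(f"  model: race_time_min = {model['intercept']:.2f} {terms}")
    lines.append(f"  R^2 = {model['r_squared']:.3f}, "
                 f"F({model['df'][0]},{model['df'][1]}) = "
                 f"{model['f_stat']:.2f}, p = {model['p_value']:.4f}")
    for warning in payload.get("warnings", []):
        lines.append(f"  warning: {warning}")
    return "\n".join(lines)
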