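"""Shared fixtures: hand-built athletes and small simulated cohorts."""
from __future__ import annotations

import math

import numpy as np
import pytest

from xcprofile.cohort import GeneratorConfig, TrueAthleteState
from xcprofile.pipeline import run_simulate


def make_athlete(po_x2_w: float = 200.0, po_x4_w: float = 260.0,
                 baseline: float = 1.0, mass_kg: float = 67.0,
                 athlete_id: str = "T001",
                 **marker_overrides: float) -> TrueAthleteState:
    """Athlete with an exact exponential lactate curve through 2/4 mmol/L."""
    markers = {"po_x2": po_x2_w / mass_kg, "po_x4": po_x4_w / mass_kg,
               "po_vo2max": 5.3, "cp": 3.9, "p_1min": 7.4,
               "p_30s": 10.4, "p_sprint": 13.5}
    markers.update(marker_overrides)
    k = math.log((4.0 - baseline) / (2.0 - baseline)) / (po_x4_w - po_x2_w)
    a = (2.0 - baseline) * math.exp(-k * po_x2_w)
    return TrueAthleteState(
        athlete_id=athlete_id, mass_kg=mass_kg, latent_ability=0.0,
        markers_wkg=markers, baseline_lactate=baseline, lactate_a=a,
        lactate_k=k, race_time_min=80.0, age_yr=16.0, height_cm=176.7)


@pytest.fixture
def easy_athlete() -> TrueAthleteState:
    """Wide 2-4 mmol/L spread: cubic fit recovers thresholds within 1 W."""
    return make_athlete(po_x2_w=200.0, po_x4_w=260.0)


@pytest.fixture(scope="session")
def default_cohort_dir(tmp_path_factory) -> str:
    """Default 10-athlete cohort (seed 42) written to disk once."""
    out = tmp_path_factory.mktemp("cohort42")
    run_simulate(out, GeneratorConfig(n_athletes=10, seed=42), force=True)
    return str(out)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
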