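"""Shared fixtures: small deterministic records and cohorts, a trained pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from hypowatch.records import HemodynamicRecord, MedicationEvent
from hypowatch.simulate import SimulationConfig, simulate_cohort
from hypowatch.windows import WindowSpec


def make_flat_record(
    n: int = 600,
    map_level: float = 80.0,
    hr_level: float = 85.0,
    pp: float = 40.0,
    record_id: str = "flat",
    age: float = 60.0,
    medications: list | None = None,
) -> HemodynamicRecord:
    """A fully valid constant record: every window passes every check."""
    map_ = np.full(n, map_level)
    sbp = map_ + 2.0 * pp / 3.0
    return HemodynamicRecord(
        record_id=record_id,
        hr=np.full(n, hr_level),
        sbp=sbp,
        dbp=sbp - pp,
        map=map_,
        age=age,
        medications=medications or [],
    )


@pytest.fixture
def flat_record() -> HemodynamicRecord:
    return make_flat_record()


@pytest.fixture
def dosed_record() -> HemodynamicRecord:
    """Flat record with one raising and one lowering medication event."""
    meds = [
        MedicationEvent(minute_index=100, drug_name="dopamine", dose=5.0),
        MedicationEvent(minute_index=130, drug_name="lasix", dose=2.0),
    ]
    return make_flat_record(record_id="dosed", medications=meds)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-record messy cohort: episodes, precursors, gaps, artifacts, meds."""
    config = SimulationConfig(
        n_records=12,
        duration_median_minutes=900,
        duration_sigma=0.15,
        episode_rate=1.5,
        precursor_map_slope=-0.2,
        precursor_pp_narrow=0.3,
        precursor_var_mult=2.0,
        missing_rate=0.01,
        artifact_rate=0.005,
        med_response=True,
        seed=5,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Episode-bearing cohort with no missing data or artifacts."""
    config = SimulationConfig(
        n_records=10,
        duration_median_minutes=900,
        duration_sigma=0.1,
        episode_rate=1.5,
        precursor_map_slope=-0.2,
        precursor_pp_narrow=0.3,
        seed=9,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def default_spec() -> WindowSpec:
    return WindowSpec(30, 60)


@pytest.fixture(scope="session")
def fitted_pipeline(clean_cohort):
    """A HypotensionResults trained on the clean cohort (for monitor/API tests)."""
    from hypowatch.api import HypotensionModel

    model = HypotensionModel(clean_cohort.records, window_spec=WindowSpec(30, 60))
    return model.fit(seed=3)
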