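import numpy as np
import pandas as pd
import pytest

import adhtraj as at


def brute_force_calendar(fills, horizon):
    """Day-by-day stockpiling oracle: an on-hand pill counter is topped up by
    each fill on its day and consumed one per covered day, independent of the
    pointer algorithm under test."""
    stock = 0.0
    covered = np.zeros(horizon, dtype=bool)
    fills = sorted((int(d), int(s)) for d, s in fills)
    i = 0
    day = 0
    while day < horizon:
        while i < len(fills) and fills[i][0] == day:
            stock += fills[i][1]
            i += 1
        if stock > 0:
            covered[day] = True
            stock -= 1
        day += 1
    return covered


@pytest.fixture(scope="session")
def paper5_scenario():
    return at.default_scenario("paper5", n_patients=1798, seed=42)


@pytest.fixture(scope="session")
def paper5_cohort(paper5_scenario):
    return at.simulate_panel(paper5_scenario)


@pytest.fixture(scope="session")
def paper5_fit(paper5_cohort):
    return at.fit_em(paper5_cohort.panel, at.TrajectorySpec.common(5, 3),
                     starts=5, seed=0)


@pytest.fixture()
def ten_patient_tables():
    """One clean patient, eight single-rule violators, one patient with no
    qualifying fill (dropped before the filter sequence starts)."""
    cfg = at.ClaimsConfig(violators=(
        "age", "enrollment", "diagnosis", "baseline_antifibrotic",
        "excluded_care", "comorbid_exclusion", "pirfenidone_overlap", "death",
    ))
    scen = at.default_scenario("one_group_null", n_patients=1, seed=3)
    cohort = at.simulate_claims(scen, at.simulate_panel(scen), cfg)
    fills = pd.concat([
        cohort.fills,
        pd.DataFrame([{"patient_id": "nofill", "day": 4,
                       "days_supply": 30, "drug": "pirfenidone"}]),
    ], ignore_index=True)
    cov = pd.concat([
        cohort.covariates,
        pd.DataFrame([{"patient_id": "nofill", "age": 80, "female": 0,
                       "nonwhite": 0, "region": "West",
                       "deprivation_score": 10.0, "comorbidity_count": 1,
                       "medication_count": 3, "any_hospitalization": 0,
                       "lung_transplant": 0, "snf": 0, "ltc": 0, "hospice": 0,
                       "dual_eligible": 0, "death_day": np.nan}]),
    ], ignore_index=True)
    return {"fills": fills, "enrollment": cohort.enrollment,
            "diagnoses": cohort.diagnoses, "covariates": cov}
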