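import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bpagree import CohortData, DeviceProfile, SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default anchored-device cohort (40 patients, seed 7)."""
    cohort, truth = simulate_cohort(SimConfig(seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def identity_cohort():
    """Same conditions but a perfectly calibrated noiseless test device."""
    cohort, truth = simulate_cohort(SimConfig(seed=7), profile_test=DeviceProfile.identity())
    return cohort, truth


@pytest.fixture(scope="session")
def affine_exact_cohort():
    """Deterministic cohort: no fluctuation, no noise, no dip; test = 20 + 0.8x."""
    cfg = SimConfig(
        seed=11,
        within_sd_sbp=0.0,
        within_sd_dbp=0.0,
        ref_noise=0.0,
        night_dip_sbp=0.0,
        night_dip_dbp=0.0,
        day_compliance=1.0,
        night_compliance=1.0,
    )
    profile = DeviceProfile(
        alpha_sbp=20.0, beta_sbp=0.8, alpha_dbp=20.0, beta_dbp=0.8
    )
    cohort, truth = simulate_cohort(cfg, profile_test=profile)
    return cohort, truth


def make_cohort(rows):
    """Build a CohortData from (patient, device, 'HH:MM' or timestamp, sbp, dbp) tuples."""
    recs = []
    for pid, device, time, sbp, dbp in rows:
        if isinstance(time, str) and len(time) == 5:
            time = f"2022-03-01T{time}"
        recs.append(
            {
                "patient_id": pid,
                "device": device,
                "time": pd.Timestamp(time),
                "sbp": float(sbp),
                "dbp": float(dbp),
            }
        )
    return CohortData(pd.DataFrame(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
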