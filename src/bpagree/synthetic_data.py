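"""Synthetic 24-h two-device blood-pressure cohorts with known ground truth.

The generator emulates the measurement structure of a smartwatch-vs-ABPM
validation study: an ABPM reference sampling every 15 min by day
(08:00-23:59) and every 30 min by night (00:00-07:59), and a manually
triggered test device measured shortly after a subset of ABPM readings
(high compliance by day, low by night).

The latent blood pressure of patient *i* at slot *t* is

    x_i(t) = m_i - dip * night(t) + f_i(t)

with per-patient daytime level ``m_i ~ N(pop_mean, between_sd**2)``, a
step-function nocturnal dip, and a stationary AR(1) fluctuation ``f_i``
with marginal SD ``within_sd`` and lag-1 autocorrelation ``ar1_rho`` at
the 15-min spacing.  Systolic and diastolic channels are generated
jointly so that the patient-level pulse pressure is ``~N(pop_mean_sbp -
pop_mean_dbp, pp_between_sd**2)``.

Device readings are affine transforms of the latent value plus noise:

    y = alpha + beta * x(t) + e,   e ~ N(0, noise**2)

The reference is the identity device (alpha=0, beta=1) with noise
``ref_noise``; the default test profile is *calibration-anchored*
(beta < 1), which compresses readings toward a central point and is the
failure mode the analysis modules are designed to expose.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_data import REFERENCE, TEST, CohortData

#: Start of the simulated 24-h session (arbitrary date; 08:00 by protocol).
SESSION_START = pd.Timestamp("2022-03-01 08:00")

_MIN_PULSE_PRESSURE = 5.0  # mmHg floor between latent sbp and dbp
_MAX_RESAMPLE = 100


@dataclasses.dataclass(frozen=True)
class DeviceProfile:
    """Affine error model of one device, per channel.

    ``alpha`` is the differential (constant) bias in mmHg, ``beta`` the
    proportional bias (unitless; beta < 1 compresses toward a calibration
    point), and ``noise`` the SD of the device's own measurement error.
    """

    alpha_sbp: float = 0.0
    beta_sbp: float = 1.0
    noise_sbp: float = 0.0
    alpha_dbp: float = 0.0
    beta_dbp: float = 1.0
    noise_dbp: float = 0.0

    def __post_init__(self):
        if self.beta_sbp <= 0 or self.beta_dbp <= 0:
            raise ValueError("proportional bias beta must be positive")
        if self.noise_sbp < 0 or self.noise_dbp < 0:
            raise ValueError("device noise SD must be non-negative")

    @classmethod
    def identity(cls, noise_sbp: float = 0.0, noise_dbp: float = 0.0) -> "DeviceProfile":
        """A perfectly calibrated device (alpha=0, beta=1)."""
        return cls(noise_sbp=noise_sbp, noise_dbp=noise_dbp)

    @classmethod
    def anchored_smartwatch(cls) -> "DeviceProfile":
        """Default test profile: a calibration-anchored smartwatch.

        alpha/beta per channel (systolic 50.1 / 0.65, diastolic
        26.5 / 0.76) are magnitudes reported for a CE-cleared wrist
        device validated against 24-h ABPM; the noise SDs are set low
        (5 / 4 mmHg) because such devices show far less short-term
        variability than the oscillometric reference.
        """
        return cls(
            alpha_sbp=50.1,
            beta_sbp=0.65,
            noise_sbp=5.0,
            alpha_dbp=26.5,
            beta_dbp=0.76,
            noise_dbp=4.0,
        )


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Cohort-level generative parameters.

    Defaults reproduce the study conditions: 40 patients, 24-h mean BP
    130/80 mmHg with between-patient SDs 12/10, within-day (daytime)
    SDs 19.1/14.8, a 12/8 mmHg nocturnal dip, reference device noise
    4 mmHg, and compliance rates giving ~28 daytime and ~3 night-time
    test measurements per patient.
    """

    n_patients: int = 40
    pop_mean_sbp: float = 130.0
    pop_mean_dbp: float = 80.0
    between_sd_sbp: float = 12.0
    between_sd_dbp: float = 10.0
    within_sd_sbp: float = 19.1
    within_sd_dbp: float = 14.8
    ar1_rho: float = 0.3
    night_dip_sbp: float = 12.0
    night_dip_dbp: float = 8.0
    ref_noise: float = 4.0
    day_compliance: float = 0.44
    night_compliance: float = 0.19
    pp_between_sd: float = 6.0
    within_corr: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in (
            "between_sd_sbp",
            "between_sd_dbp",
            "within_sd_sbp",
            "within_sd_dbp",
            "ref_noise",
            "pp_between_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        for name in ("day_compliance", "night_compliance"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1 < self.within_corr < 1:
            raise ValueError("within_corr must be in (-1, 1)")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Latent values retained alongside a generated cohort.

    ``patients`` has one row per patient (daytime latent level per
    channel); ``values`` one row per ABPM slot (latent BP at that time).
    """

    patients: pd.DataFrame
    values: pd.DataFrame


def abpm_schedule(start: pd.Timestamp = SESSION_START):
    """The 24-h ABPM slot grid: 64 daytime + 16 night slots.

    Returns ``(times, night)`` where ``night`` flags the 00:00-07:59
    window.  Day slots are every 15 min over 16 h, night every 30 min
    over 8 h.
    """
    day_offsets = np.arange(0, 16 * 60, 15)
    night_offsets = np.arange(16 * 60, 24 * 60, 30)
    offsets = np.concatenate([day_offsets, night_offsets])
    night = np.concatenate(
        [np.zeros(len(day_offsets), bool), np.ones(len(night_offsets), bool)]
    )
    times = start + pd.to_timedelta(offsets, unit="min")
    return times, night


def _patient_levels(config: SimConfig, rng: np.random.Generator):
    """Draw correlated (sbp, dbp) daytime levels for one patient.

    The correlation is chosen so that the patient-level pulse pressure
    has SD ``pp_between_sd``; draws with pulse pressure below 10 mmHg
    are rejected and redrawn.
    """
    bs, bd = config.between_sd_sbp, config.between_sd_dbp
    if bs > 0 and bd > 0:
        rho = (bs**2 + bd**2 - config.pp_between_sd**2) / (2 * bs * bd)
        rho = float(np.clip(rho, -0.99, 0.99))
    else:
        rho = 0.0
    for _ in range(_MAX_RESAMPLE):
        z1, z2 = rng.standard_normal(2)
        mean_s = config.pop_mean_sbp + bs * z1
        mean_d = config.pop_mean_dbp + bd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        if mean_s - mean_d >= 10.0:
            return mean_s, mean_d
    return mean_s, mean_d - 10.0  # pathological config; force a valid gap


def _ar1_pair(config: SimConfig, dt_min: np.ndarray, rng: np.random.Generator):
    """Correlated stationary AR(1) fluctuations for both channels."""
    n = len(dt_min) + 1
    c = config.within_corr
    e1 = rng.standard_normal(n)
    e2 = c * e1 + np.sqrt(1 - c**2) * rng.standard_normal(n)
    phi = config.ar1_rho ** (dt_min / 15.0) if config.ar1_rho > 0 else np.zeros_like(dt_min, dtype=float)
    f_s = np.empty(n)
    f_d = np.empty(n)
    f_s[0] = config.within_sd_sbp * e1[0]
    f_d[0] = config.within_sd_dbp * e2[0]
    for k in range(1, n):
        p = phi[k - 1]
        innov = np.sqrt(1 - p**2)
        f_s[k] = p * f_s[k - 1] + config.within_sd_sbp * innov * e1[k]
        f_d[k] = p * f_d[k - 1] + config.within_sd_dbp * innov * e2[k]
    return f_s, f_d


def _readings(
    latent_s: np.ndarray,
    latent_d: np.ndarray,
    alpha_s: float,
    beta_s: float,
    noise_s: float,
    alpha_d: float,
    beta_d: float,
    noise_d: float,
    rng: np.random.Generator,
):
    """Apply an affine device model; resample noise where dbp < sbp fails."""
    n = len(latent_s)
    sbp = alpha_s + beta_s * latent_s + noise_s * rng.standard_normal(n)
    dbp = alpha_d + beta_d * latent_d + noise_d * rng.standard_normal(n)
    for _ in range(_MAX_RESAMPLE):
        bad = ~((dbp >= 40.0) & (dbp < sbp) & (sbp <= 300.0))
        if not bad.any():
            break
        if noise_s == 0 and noise_d == 0:
            break  # nothing to resample; clamp below
        m = int(bad.sum())
        sbp[bad] = alpha_s + beta_s * latent_s[bad] + noise_s * rng.standard_normal(m)
        dbp[bad] = alpha_d + beta_d * latent_d[bad] + noise_d * rng.standard_normal(m)
    # last-resort clamps for extreme tails: keep 40 <= dbp < sbp <= 300
    sbp = np.clip(sbp, 41.0, 300.0)
    dbp = np.clip(dbp, 40.0, sbp - 1.0)
    return sbp, dbp


def simulate_patient(
    config: SimConfig,
    profile_test: DeviceProfile | None = None,
    profile_ref: DeviceProfile | None = None,
    patient_seed=None,
    rng: np.random.Generator | None = None,
    patient_id: str = "P001",
    start: pd.Timestamp = SESSION_START,
):
    """Simulate one patient's 24-h series for both devices.

    Reference readings occur at every ABPM slot; test readings at the
    slots retained by Bernoulli compliance sampling, time-stamped 1-5 min
    after the slot (manual activation) but measuring the same latent BP.
    Degenerate noiseless configs are allowed and yield exact series for
    oracle tests.

    Returns ``(ref_frame, test_frame, truth)`` where the frames are in
    :class:`~bpagree.core_data.CohortData` column layout.
    """
    if rng is None:
        rng = np.random.default_rng(patient_seed)
    if profile_test is None:
        profile_test = DeviceProfile.anchored_smartwatch()
    if profile_ref is None:
        profile_ref = DeviceProfile.identity(
            noise_sbp=config.ref_noise, noise_dbp=config.ref_noise
        )

    times, night = abpm_schedule(start)
    dt_min = np.diff(
        (times - times[0]) / pd.Timedelta(minutes=1)
    ).astype(float)

    mean_s, mean_d = _patient_levels(config, rng)
    f_s, f_d = _ar1_pair(config, dt_min, rng)
    latent_s = mean_s - config.night_dip_sbp * night + f_s
    latent_d = mean_d - config.night_dip_dbp * night + f_d
    latent_d = np.minimum(latent_d, latent_s - _MIN_PULSE_PRESSURE)

    ref_sbp, ref_dbp = _readings(
        latent_s,
        latent_d,
        profile_ref.alpha_sbp,
        profile_ref.beta_sbp,
        profile_ref.noise_sbp,
        profile_ref.alpha_dbp,
        profile_ref.beta_dbp,
        profile_ref.noise_dbp,
        rng,
    )

    p_keep = np.where(night, config.night_compliance, config.day_compliance)
    keep = rng.random(len(times)) < p_keep
    delays = rng.integers(1, 6, size=int(keep.sum()))
    test_times = times[keep] + pd.to_timedelta(delays, unit="min")
    test_sbp, test_dbp = _readings(
        latent_s[keep],
        latent_d[keep],
        profile_test.alpha_sbp,
        profile_test.beta_sbp,
        profile_test.noise_sbp,
        profile_test.alpha_dbp,
        profile_test.beta_dbp,
        profile_test.noise_dbp,
        rng,
    )

    ref = pd.DataFrame(
        {
            "patient_id": patient_id,
            "device": REFERENCE,
            "time": times,
            "sbp": ref_sbp,
            "dbp": ref_dbp,
        }
    )
    test = pd.DataFrame(
        {
            "patient_id": patient_id,
            "device": TEST,
            "time": test_times,
            "sbp": test_sbp,
            "dbp": test_dbp,
        }
    )
    truth = GroundTruth(
        patients=pd.DataFrame(
            {"patient_id": [patient_id], "mean_sbp": [mean_s], "mean_dbp": [mean_d]}
        ),
        values=pd.DataFrame(
            {
                "patient_id": patient_id,
                "timestamp": times,
                "latent_sbp": latent_s,
                "latent_dbp": latent_d,
            }
        ),
    )
    return ref, test, truth


def simulate_cohort(
    config: SimConfig,
    profile_test: DeviceProfile | None = None,
    profile_ref: DeviceProfile | None = None,
):
    """Simulate a full cohort; deterministic under ``config.seed``.

    Per-patient generators are spawned from the master seed, so the
    output is bit-reproducible and independent of patient order.

    Returns ``(cohort, truth)``.
    """
    if config.n_patients < 2:
        raise ValueError("need at least 2 patients (between-patient variance)")
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    ref_frames, test_frames, truth_p, truth_v = [], [], [], []
    for i, child in enumerate(children):
        pid = f"P{i + 1:03d}"
        ref, test, truth = simulate_patient(
            config,
            profile_test=profile_test,
            profile_ref=profile_ref,
            rng=np.random.default_rng(child),
            patient_id=pid,
        )
        ref_frames.append(ref)
        test_frames.append(test)
        truth_p.append(truth.patients)
        truth_v.append(truth.values)
    frame = pd.concat(ref_frames + test_frames, ignore_index=True)
    cohort = CohortData(frame)
    truth = GroundTruth(
        patients=pd.concat(truth_p, ignore_index=True),
        values=pd.concat(truth_v, ignore_index=True),
    )
    return cohort, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the per-slot latent values as a sidecar CSV."""
    out = truth.values.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)
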