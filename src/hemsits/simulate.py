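"""Synthetic HEMS mission generator.

Emulates a three-base regional helicopter-EMS registry extract: one row per
mission with alarm/takeoff/on-scene timestamps, base, mission category
flags, GPS position, and a per-patient sidecar table (age, sex, NACA
severity, ICD-10 chapter, patient-contact time).

The statistical backbone is the segmented monthly trend the downstream
interrupted-time-series analysis assumes: month t's mean response time is

    mu_t = beta0 + beta1*t + beta2*u(t - tpi) + beta3*(t - tpi)*u(t - tpi)
           + beta4 * I_winter(t) + e_t,

where u is the unit step at the intervention month tpi, I_winter indicates
October-March, and e_t is an MA(1) month shock. Individual missions draw
i.i.d. normal noise around mu_t, truncated below so that no response time
undercuts the base's start-up time (nor the mission's own alarm-to-takeoff
interval, which keeps the timeline ordered).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (DEFAULT_ICD10_POST, DEFAULT_ICD10_PRE, ICD10_CHAPTERS,
                     BaseDefinition, SimulationConfig)
from .geodesy import geodesic_direct

__all__ = ["simulate_ma1_shocks", "sample_location", "monthly_mean_trend",
           "generate_missions"]


def simulate_ma1_shocks(n_months: int, theta: float, sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a first-order moving-average shock series.

    e_t = z_t + theta * z_{t-1} with z_t i.i.d. N(0, sd^2); the lag-1
    autocorrelation is theta / (1 + theta^2) and higher lags are zero.
    """
    if not abs(theta) < 1.0:
        raise ValueError(f"ma_theta: |theta| must be < 1, got {theta!r}")
    if sd < 0:
        raise ValueError(f"sd: must be >= 0, got {sd!r}")
    if n_months < 1:
        raise ValueError(f"n_months: must be >= 1, got {n_months!r}")
    z = rng.normal(0.0, sd, size=n_months + 1)
    return z[1:] + theta * z[:-1]


def sample_location(base: BaseDefinition, max_radius_km: float,
                    rng: np.random.Generator) -> tuple[float, float]:
    """Sample a mission location area-uniformly in a geodesic disc around a
    base: uniform bearing, distance density increasing linearly to the
    radius (so the 95th-percentile distance is sqrt(0.95) of the radius)."""
    if max_radius_km <= 0:
        raise ValueError(f"max_mission_radius_km: must be > 0, got {max_radius_km!r}")
    bearing = rng.uniform(0.0, 360.0)
    distance = max_radius_km * np.sqrt(rng.uniform())
    return geodesic_direct(base.latitude, base.longitude, bearing, distance)


def monthly_mean_trend(config: SimulationConfig) -> np.ndarray:
    """Deterministic monthly mean response time (no shocks), minutes."""
    t = np.arange(config.n_months)
    step = (t >= config.tpi).astype(float)
    ramp = (t - config.tpi) * step
    start = pd.Period(config.study_start, freq="M")
    cal = np.array([(start + k).month for k in t])
    winter = np.isin(cal, (10, 11, 12, 1, 2, 3)).astype(float)
    return (config.beta0 + config.beta1 * t + config.beta2 * step
            + config.beta3 * ramp + config.beta4 * winter)


def _truncnorm_draw(mu: float, sd: float, lower: float,
                    rng: np.random.Generator) -> float:
    # inverse-CDF sampling keeps the draw a deterministic function of one
    # uniform, so the same seed yields the same table for any sd
    if sd == 0.0:
        return max(mu, lower)
    a = (lower - mu) / sd
    u = rng.uniform()
    return float(stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sd))


def generate_missions(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a mission table and its per-patient sidecar table.

    Returns ``(missions, patients)``. Missions carry ground-truth columns
    (``true_scramble``, ``month_index``) so tests can compare classifier
    output against what the generator actually planted. The same
    ``config.seed`` reproduces both tables bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    mu = monthly_mean_trend(config)
    shocks = simulate_ma1_shocks(config.n_months, config.ma_theta,
                                 config.month_shock_sd, rng)
    month_mean = mu + shocks
    start = pd.Period(config.study_start, freq="M")
    intervention = pd.Timestamp(config.intervention_date, tz="UTC")

    mission_rows: list[dict] = []
    patient_rows: list[dict] = []
    mission_no = 0
    for t in range(config.n_months):
        period_m = start + t
        month_start = period_m.to_timestamp(how="start").tz_localize("UTC")
        n_days = period_m.days_in_month
        for base in config.bases:
            n = rng.poisson(config.missions_per_month)
            # alarm instants uniform over the month, sorted for stable output
            offsets = np.sort(rng.uniform(0.0, n_days * 24 * 60, size=n))
            for j in range(n):
                mission_no += 1
                mid = f"M{mission_no:06d}"
                alarm = month_start + pd.Timedelta(minutes=float(offsets[j]))
                is_post = alarm >= intervention
                scramble = rng.uniform() < config.scramble_prob
                if scramble:
                    takeoff_gap = rng.uniform(0.0, 2.0)
                else:
                    takeoff_gap = rng.uniform(base.startup_time,
                                              base.startup_time + 10.0)
                lower = max(base.startup_time, takeoff_gap)
                response = _truncnorm_draw(month_mean[t], config.mission_noise_sd,
                                           lower, rng)
                lat, lon = sample_location(base, config.max_mission_radius_km, rng)

                cancelled = rng.uniform() < config.p_cancelled
                u = rng.uniform()
                if u < config.p_car:
                    mtype = "car"
                elif u < config.p_car + config.p_sar:
                    mtype = "SAR"
                elif u < config.p_car + config.p_sar + config.p_secondary:
                    mtype = "secondary"
                else:
                    mtype = "primary"
                urgency = "other" if rng.uniform() < config.p_other_urgency else "acute"
                contact = rng.uniform() >= config.p_no_contact
                missing_gps = rng.uniform() < config.p_missing_gps

                naca_props = (config.naca_props_post if is_post
                              else config.naca_props_pre)
                n_pat = 0 if not contact else (
                    2 if rng.uniform() < config.p_second_patient else 1)
                on_scene = alarm + pd.Timedelta(minutes=response)
                for p in range(n_pat):
                    contact_time = on_scene if p == 0 else (
                        on_scene + pd.Timedelta(minutes=rng.uniform(1.0, 10.0)))
                    male_prob = 0.66 if is_post else 0.64
                    age_mu, age_sd = (57.0, 24.0) if is_post else (53.0, 26.0)
                    icd = DEFAULT_ICD10_POST if is_post else DEFAULT_ICD10_PRE
                    patient_rows.append({
                        "mission_id": mid,
                        "patient_index": p,
                        "age": round(_truncnorm_draw(age_mu, age_sd, 0.0, rng)),
                        "sex": "male" if rng.uniform() < male_prob else "female",
                        "naca": int(rng.choice(8, p=naca_props)),
                        "icd10_chapter": str(rng.choice(ICD10_CHAPTERS, p=icd)),
                        "contact_time": contact_time.isoformat(),
                    })
                mission_rows.append({
                    "mission_id": mid,
                    "base_id": base.base_id,
                    "alarm_time": alarm.isoformat(),
                    "takeoff_time": (alarm + pd.Timedelta(minutes=takeoff_gap)).isoformat(),
                    "on_scene_time": on_scene.isoformat(),
                    "urgency": urgency,
                    "mission_type": mtype,
                    "completed": not cancelled,
                    "patient_contact": contact and n_pat > 0,
                    "latitude": np.nan if missing_gps else round(lat, 6),
                    "longitude": np.nan if missing_gps else round(lon, 6),
                    "period": "post" if is_post else "pre",
                    "month_index": t,
                    "true_scramble": scramble,
                })
    missions = pd.DataFrame(mission_rows)
    patients = pd.DataFrame(patient_rows)
    return missions, patients
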