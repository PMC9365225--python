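"""Study configuration: helicopter bases, generator parameters, analysis knobs.

The defaults encode the Mid-Norway study conditions: three rotor-wing bases
(Trondheim, Alesund, Orland), a 24-month pre-intervention period starting
January 2017, a 12-month post period, intervention on 2019-01-07, a regional
monthly mean response time near 31 minutes with a ~1.1-minute winter
(October-March) elevation, MA(1) month-to-month error correlation, and an
in-flight-scramble probability of 0.12.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class BaseDefinition:
    """A helicopter base: identifier, WGS84 position, and start-up time.

    ``startup_time`` is the minimum minutes from alarm to take-off imposed by
    the airframe (rotor start, checklists); it lower-bounds every non-scramble
    alarm-to-takeoff interval and every response time from that base.
    """

    base_id: str
    latitude: float
    longitude: float
    startup_time: float  # minutes

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude: {self.latitude!r} outside [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude: {self.longitude!r} outside [-180, 180]")
        if self.startup_time < 0:
            raise ValueError(f"startup_time: must be >= 0, got {self.startup_time!r}")


#: The three regional rotor-wing bases with approximate coordinates and the
#: published start-up times (Trondheim H145: 3 min; Alesund AW139: 2 min;
#: Orland Sea King: 10 min).
DEFAULT_BASES = (
    BaseDefinition("trondheim", 63.4305, 10.3951, 3.0),
    BaseDefinition("alesund", 62.4722, 6.1549, 2.0),
    BaseDefinition("orland", 63.6990, 9.6040, 10.0),
)

# NACA severity score probability vectors over scores 0..7.  Shapes chosen so
# that P(NACA >= 4) is 0.615 pre / 0.682 post with period means near 3.98/4.13.
DEFAULT_NACA_PRE = (0.005, 0.015, 0.055, 0.310, 0.350, 0.170, 0.045, 0.050)
DEFAULT_NACA_POST = (0.004, 0.012, 0.042, 0.260, 0.400, 0.180, 0.052, 0.050)

# ICD-10 chapter labels and (pre-period) probabilities used for patient
# diagnoses; a mild shift toward circulatory disease is applied post.
ICD10_CHAPTERS = ("G", "I", "J", "M", "O", "R", "S-T", "other")
DEFAULT_ICD10_PRE = (0.040, 0.354, 0.057, 0.015, 0.023, 0.149, 0.295, 0.067)
DEFAULT_ICD10_POST = (0.032, 0.397, 0.062, 0.005, 0.016, 0.125, 0.303, 0.060)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic mission generator.

    The monthly mean response time follows the segmented trend
    ``beta0 + beta1*t + beta2*step + beta3*ramp + beta4*winter`` plus an MA(1)
    month shock; individual missions add i.i.d. noise around their month's
    mean, truncated below so no response time undercuts the base's start-up
    time. Month index t is 0-based at ``study_start``; the intervention occurs
    at t = ``months_pre``.
    """

    study_start: str = "2017-01"          # first calendar month, YYYY-MM
    months_pre: int = 24
    months_post: int = 12
    bases: tuple[BaseDefinition, ...] = DEFAULT_BASES
    missions_per_month: float = 28.0      # expected missions per base-month
    beta0: float = 31.05                  # min, mean response at t = 0
    beta1: float = 0.05                   # min/month, pre-intervention slope
    beta2: float = -0.13                  # min, level change at intervention
    beta3: float = -0.13                  # min/month, slope change
    beta4: float = 1.1                    # min, winter (Oct-Mar) elevation
    ma_theta: float = 0.3                 # MA(1) coefficient, |theta| < 1
    month_shock_sd: float = 1.0           # min, SD of monthly shock innovations
    mission_noise_sd: float = 10.0        # min, SD of mission-level noise
    naca_props_pre: tuple[float, ...] = DEFAULT_NACA_PRE
    naca_props_post: tuple[float, ...] = DEFAULT_NACA_POST
    scramble_prob: float = 0.12
    max_mission_radius_km: float = 110.0
    seed: int = 0
    # probabilities of planting records that the inclusion filter must drop
    p_cancelled: float = 0.03
    p_car: float = 0.01
    p_sar: float = 0.02
    p_secondary: float = 0.04
    p_other_urgency: float = 0.05
    p_no_contact: float = 0.02
    p_missing_gps: float = 0.022
    p_second_patient: float = 0.017
    intervention_date: str = "2019-01-07"

    def __post_init__(self) -> None:
        if self.months_pre <= 0:
            raise ValueError(f"months_pre: must be > 0, got {self.months_pre!r}")
        if self.months_post < 0:
            raise ValueError(f"months_post: must be >= 0, got {self.months_post!r}")
        if not self.bases:
            raise ValueError("bases: at least one base required")
        if self.missions_per_month <= 0:
            raise ValueError("missions_per_month: must be > 0")
        for name in ("naca_props_pre", "naca_props_post"):
            v = getattr(self, name)
            if len(v) != 8:
                raise ValueError(f"{name}: must have 8 entries (NACA 0-7)")
            if any(p < 0 for p in v):
                raise ValueError(f"{name}: probabilities must be >= 0")
            if abs(sum(v) - 1.0) > 1e-9:
                raise ValueError(f"{name}: must sum to 1 within 1e-9, got {sum(v)!r}")
        if not abs(self.ma_theta) < 1.0:
            raise ValueError(f"ma_theta: |theta| must be < 1, got {self.ma_theta!r}")
        for name in ("month_shock_sd", "mission_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if not 0.0 <= self.scramble_prob <= 1.0:
            raise ValueError(f"scramble_prob: must be in [0, 1], got {self.scramble_prob!r}")
        if self.max_mission_radius_km <= 0:
            raise ValueError("max_mission_radius_km: must be > 0")
        for name in ("p_cancelled", "p_car", "p_sar", "p_secondary",
                     "p_other_urgency", "p_no_contact", "p_missing_gps",
                     "p_second_patient"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1]")
        # the intervention date defines the pre/post split and must land in
        # the month the segmented trend breaks at (index months_pre)
        import pandas as _pd
        tpi_month = _pd.Period(self.study_start, freq="M") + self.months_pre
        if _pd.Period(self.intervention_date, freq="M") != tpi_month:
            raise ValueError(
                f"intervention_date: {self.intervention_date!r} is not in "
                f"the intervention month {tpi_month} "
                f"(study_start + months_pre)")

    @property
    def n_months(self) -> int:
        return self.months_pre + self.months_post

    @property
    def tpi(self) -> int:
        """0-based month index of the intervention month."""
        return self.months_pre


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis stages, separate from data generation."""

    intervention_date: str = "2019-01-07"
    z_threshold: float = 3.0          # SD units for outlier-month exclusion
    quantile: float = 0.95            # distance-filter quantile for hulls
    threshold_minutes: float = 45.0   # national response-time goal
    error_candidates: tuple[str, ...] = ("white", "ma1", "ar1", "sma12")
    winter_months: tuple[int, ...] = (10, 11, 12, 1, 2, 3)
    holm_adjust: bool = False
    welch_t: bool = True

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold: must be > 0")
        if not 0.0 < self.quantile <= 1.0:
            raise ValueError("quantile: must be in (0, 1]")
        if self.threshold_minutes <= 0:
            raise ValueError("threshold_minutes: must be > 0")


_SCALAR_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)
                  if f.name not in ("bases", "naca_props_pre", "naca_props_post")}
_ANALYSIS_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def write_config(path: str | Path, sim: SimulationConfig,
                 analysis: AnalysisConfig | None = None) -> None:
    """Write a flat ``key = value`` configuration file."""
    lines = []
    for name in sorted(_SCALAR_FIELDS):
        lines.append(f"{name} = {getattr(sim, name)}")
    lines.append("naca_props_pre = " + ",".join(map(str, sim.naca_props_pre)))
    lines.append("naca_props_post = " + ",".join(map(str, sim.naca_props_post)))
    lines.append("bases = " + ";".join(
        f"{b.base_id},{b.latitude},{b.longitude},{b.startup_time}"
        for b in sim.bases))
    if analysis is not None:
        for name in sorted(_ANALYSIS_FIELDS):
            v = getattr(analysis, name)
            if isinstance(v, tuple):
                v = ",".join(map(str, v))
            lines.append(f"{name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Read a flat ``key = value`` file written by :func:`write_config`.

    Unknown keys raise ``ValueError`` naming the key; missing keys take their
    documented defaults.
    """
    sim_kwargs: dict = {}
    ana_kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "bases":
            bases = []
            for chunk in value.split(";"):
                bid, lat, lon, st = chunk.split(",")
                bases.append(BaseDefinition(bid.strip(), float(lat), float(lon), float(st)))
            sim_kwargs["bases"] = tuple(bases)
        elif key in ("naca_props_pre", "naca_props_post"):
            sim_kwargs[key] = tuple(float(x) for x in value.split(","))
        elif key in _SCALAR_FIELDS:
            sim_kwargs[key] = _coerce(SimulationConfig, key, value)
        elif key == "error_candidates":
            ana_kwargs[key] = tuple(x.strip() for x in value.split(","))
        elif key == "winter_months":
            ana_kwargs[key] = tuple(int(x) for x in value.split(","))
        elif key in _ANALYSIS_FIELDS:
            ana_kwargs[key] = _coerce(AnalysisConfig, key, value)
        else:
            raise ValueError(f"unknown configuration key: {key!r}")
    return SimulationConfig(**sim_kwargs), AnalysisConfig(**ana_kwargs)


def _coerce(cls, key: str, value: str):
    ftype = {f.name: f.type for f in dataclasses.fields(cls)}[key]
    if "bool" in str(ftype):
        return value.lower() in ("1", "true", "yes")
    if "int" in str(ftype):
        return int(value)
    if "float" in str(ftype):
        return float(value)
    return value
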