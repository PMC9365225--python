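"""Mission-level data model, CSV ingestion, inclusion filtering, and derived
timeline quantities.

The analysis population is: completed, primary, acute helicopter missions
with patient contact. Everything else is excluded with a reason, tallied in
a fixed priority order so the flow-chart counts are deterministic:

    cancelled/aborted -> rapid-response car -> SAR -> secondary
    -> not acute -> no patient contact -> missing/invalid timeline

Missing GPS coordinates do not exclude a mission here; they only make it
ineligible for the map-based service-area analysis (the response-time and
service-area denominators differ by design).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord", "MissionRecord", "ExclusionTally",
    "EXCLUSION_ORDER", "load_missions", "save_missions",
    "apply_inclusion_criteria", "response_time", "response_time_minutes",
    "is_inflight_scramble", "collapse_multipatient", "assign_period",
]

SCRAMBLE_THRESHOLD_MIN = 2.0  # alarm-to-takeoff below this means airborne


@dataclass(frozen=True)
class PatientRecord:
    """One patient on a mission: demographics and severity."""

    age: float
    sex: str
    naca: int
    icd10_chapter: str = "other"
    contact_time: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.naca <= 7:
            raise ValueError(f"naca: must be in [0, 7], got {self.naca!r}")
        if self.age < 0:
            raise ValueError(f"age: must be >= 0, got {self.age!r}")


@dataclass(frozen=True)
class MissionRecord:
    """One helicopter mission with its timeline, location and patients."""

    mission_id: str
    alarm_time: pd.Timestamp | None
    takeoff_time: pd.Timestamp | None
    on_scene_time: pd.Timestamp | None
    base_id: str
    urgency: str = "acute"
    mission_type: str = "primary"
    completed: bool = True
    patient_contact: bool = True
    latitude: float | None = None
    longitude: float | None = None
    period: str | None = None
    patients: tuple[PatientRecord, ...] = field(default_factory=tuple)


EXCLUSION_ORDER = (
    "cancelled or aborted",
    "rapid-response car",
    "SAR mission",
    "secondary mission",
    "not acute",
    "no patient contact",
    "missing timeline",
)


@dataclass
class ExclusionTally:
    """Flow-chart bookkeeping: every input record is either included or
    counted under exactly one exclusion reason."""

    total: int = 0
    included: int = 0
    excluded: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_ORDER})
    missing_gps: int = 0  # informational: map-ineligible, still included

    def check_conservation(self) -> None:
        if self.included + sum(self.excluded.values()) != self.total:
            raise AssertionError("exclusion tally does not conserve records")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": "total", "count": self.total},
                {"category": "included", "count": self.included}]
        rows += [{"category": f"excluded: {r}", "count": c}
                 for r, c in self.excluded.items()]
        rows.append({"category": "map-ineligible (missing GPS)",
                     "count": self.missing_gps})
        return pd.DataFrame(rows)


_TIME_COLS = ("alarm_time", "takeoff_time", "on_scene_time")


def load_missions(path: str | Path,
                  patients_path: str | Path | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read mission (and optional patient sidecar) CSVs with ISO-8601
    timestamps, returning timezone-aware tables."""
    df = pd.read_csv(path)
    for col in _TIME_COLS:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], utc=True, errors="coerce")
    patients = None
    if patients_path is not None:
        patients = pd.read_csv(patients_path)
        if "contact_time" in patients.columns:
            patients["contact_time"] = pd.to_datetime(
                patients["contact_time"], utc=True, errors="coerce")
    return df, patients


def save_missions(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in _TIME_COLS:
        if col in out.columns and pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].map(lambda x: x.isoformat() if pd.notna(x) else "")
    out.to_csv(path, index=False)


def assign_period(df: pd.DataFrame, intervention_date: str) -> pd.DataFrame:
    """Derive the pre/post period from the alarm instant versus the
    intervention date; the boundary day belongs to the post period."""
    cutoff = pd.Timestamp(intervention_date, tz="UTC")
    out = df.copy()
    out["period"] = np.where(out["alarm_time"] >= cutoff, "post", "pre")
    return out


def apply_inclusion_criteria(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Filter to completed, primary, acute missions with patient contact.

    Each dropped record is tallied under its first matching reason in
    :data:`EXCLUSION_ORDER`; unparseable or inverted timelines are excluded
    as "missing timeline" rather than silently passed on.
    """
    tally = ExclusionTally(total=len(df))
    if len(df) == 0:
        return df.copy(), tally

    reason = pd.Series("", index=df.index, dtype=object)

    def mark(mask: pd.Series, label: str) -> None:
        mask = mask & (reason == "")
        reason[mask] = label

    completed = df.get("completed", pd.Series(True, index=df.index))
    if completed.dtype == object:
        completed = completed.astype(str).str.lower().isin(("true", "1", "yes"))
    contact = df.get("patient_contact", pd.Series(True, index=df.index))
    if contact.dtype == object:
        contact = contact.astype(str).str.lower().isin(("true", "1", "yes"))

    mark(~completed.astype(bool), "cancelled or aborted")
    mark(df["mission_type"] == "car", "rapid-response car")
    mark(df["mission_type"] == "SAR", "SAR mission")
    mark(df["mission_type"] == "secondary", "secondary mission")
    mark(df["urgency"] != "acute", "not acute")
    mark(~contact.astype(bool), "no patient contact")

    bad_time = (df["alarm_time"].isna() | df["on_scene_time"].isna()
                | (df["on_scene_time"] <= df["alarm_time"]))
    mark(bad_time, "missing timeline")

    included = df[reason == ""].copy()
    for label in EXCLUSION_ORDER:
        tally.excluded[label] = int((reason == label).sum())
    tally.included = len(included)
    if "latitude" in included.columns:
        tally.missing_gps = int((included["latitude"].isna()
                                 | included["longitude"].isna()).sum())
    tally.check_conservation()
    return included, tally


def response_time_minutes(df: pd.DataFrame) -> pd.Series:
    """Vectorised alarm-to-on-scene interval in decimal minutes.

    Missing timestamps give NaN; non-positive intervals also give NaN (they
    are data errors that the inclusion filter flags for review upstream).
    """
    delta = (df["on_scene_time"] - df["alarm_time"]).dt.total_seconds() / 60.0
    return delta.where(delta > 0)


def response_time(record: MissionRecord) -> float:
    """Alarm-to-on-scene interval of one mission, decimal minutes."""
    if record.alarm_time is None or record.on_scene_time is None or (
            pd.isna(record.alarm_time) or pd.isna(record.on_scene_time)):
        return float("nan")
    minutes = (record.on_scene_time - record.alarm_time).total_seconds() / 60.0
    if minutes <= 0:
        raise ValueError(
            f"mission {record.mission_id}: non-positive response interval "
            f"({minutes:.2f} min) — timeline needs review")
    return minutes


def is_inflight_scramble(record: MissionRecord) -> bool | None:
    """True when the alarm-to-takeoff interval is strictly below 2 minutes —
    a turnaround only an already-airborne crew can achieve. ``None`` when the
    takeoff timestamp is missing."""
    if record.alarm_time is None or record.takeoff_time is None or (
            pd.isna(record.alarm_time) or pd.isna(record.takeoff_time)):
        return None
    minutes = (record.takeoff_time - record.alarm_time).total_seconds() / 60.0
    return minutes < SCRAMBLE_THRESHOLD_MIN


def scramble_flags(df: pd.DataFrame) -> pd.Series:
    """Vectorised in-flight-scramble classification."""
    gap = (df["takeoff_time"] - df["alarm_time"]).dt.total_seconds() / 60.0
    return gap < SCRAMBLE_THRESHOLD_MIN


def collapse_multipatient(record: MissionRecord) -> MissionRecord:
    """Collapse a multi-patient mission to a single row whose on-scene time
    is the earliest patient contact; all patients stay on the record for
    descriptive analyses."""
    if len(record.patients) == 0:
        raise ValueError(
            f"mission {record.mission_id}: no patients — excluded as "
            "'no patient contact'")
    contacts = [p.contact_time for p in record.patients
                if p.contact_time is not None and pd.notna(p.contact_time)]
    if not contacts:
        return record
    return replace(record, on_scene_time=min(contacts))
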