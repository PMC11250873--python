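"""Canonical schema for vehicle-in-fatal-crash tables.

One row is one vehicle involved in a fatal multivehicle crash, carrying the
VIN-decoded availability codes of two driver warning systems (DWS) — a
forward collision warning system (FCWS) and blind spot monitoring (BSM) —
plus the driver, road and crash covariates used in the ordinal analysis.
Categorical values are serialized with the exact strings used in the study's
descriptive tables; unparseable or absent values are the sentinel "Missing".
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Mapping

import numpy as np
import pandas as pd

MISSING = "Missing"

#: VIN availability codes for a single warning system.
DWS_CODES = ("Standard", "Optional", "Not Available")

GENDER = ("Female", "Male")
AREA_TYPE = ("Urban", "Rural")
FUNCTIONAL_CLASS = (
    "Interstate",
    "Freeway or expressway",
    "Principal arterial",
    "Minor arterial",
    "Major collector",
    "Minor collector",
    "Local",
)
N_LANES = (
    "No traffic way access",
    "One lane",
    "Two lanes",
    "Three lanes",
    "Four lanes",
    "Five lanes",
    "Six lanes",
    "Seven or more lanes",
)
LIGHT_CONDITION = ("Daylight", "Dark", "Dawn", "Dusk")
SURFACE_CONDITION = ("Dry", "Wet", "Ice, snow, mud, dirt, oil, or water")
PRE_CRASH_STABILITY = (
    "Tracking",
    "Skidding laterally",
    "Skidding longitudinally",
    "Not specific",
)
SEASON = ("Winter", "Spring", "Summer", "Fall")
TIME_OF_DAY = (
    "12 a.m.–3 a.m.",
    "3 a.m.–6 a.m.",
    "6 a.m.–9 a.m.",
    "9 a.m. to 12 p.m.",
    "12 p.m.–3 p.m.",
    "3 p.m.–6 p.m.",
    "6 p.m.–9 p.m.",
    "9 p.m. to 12 a.m.",
)
WEATHER = (
    "Clear",
    "Cloudy",
    "Rain",
    "Snow, fog/smoke/smog, or other adverse condition",
)
MANNER_OF_COLLISION = (
    "Head-on",
    "Rear-end",
    "Angle",
    "Sideswipe - opposite direction",
    "Sideswipe - same direction",
)

#: Driver age bands used throughout: [16, 24), [24, 40], (40, 65], (65, ...).
AGE_BANDS = (
    "Less than 24 years",
    "≥24, ≤ 40 years",
    ">40, ≤ 65 years",
    "Greater than 65 years",
)

YEAR_MIN, YEAR_MAX = 2016, 2020

#: column -> allowed categorical values (flags and numerics handled separately)
ENUM_COLUMNS: dict[str, tuple[str, ...]] = {
    "fcws_code": DWS_CODES,
    "bsm_code": DWS_CODES,
    "gender": GENDER,
    "area_type": AREA_TYPE,
    "functional_class": FUNCTIONAL_CLASS,
    "n_lanes": N_LANES,
    "light_condition": LIGHT_CONDITION,
    "surface_condition": SURFACE_CONDITION,
    "pre_crash_stability": PRE_CRASH_STABILITY,
    "season": SEASON,
    "time_of_day": TIME_OF_DAY,
    "weather": WEATHER,
    "manner_of_collision": MANNER_OF_COLLISION,
}

#: 0/1 flag columns
FLAG_COLUMNS = ("drink_drive", "speeding", "intersection", "work_zone")

#: numeric columns and their parsers
NUMERIC_COLUMNS = ("year", "latitude", "longitude", "n_vehicles", "driver_age")

#: full canonical column order
COLUMNS = (
    "crash_id",
    "year",
    "latitude",
    "longitude",
    "fcws_code",
    "bsm_code",
    "n_vehicles",
    "driver_age",
    "gender",
    "drink_drive",
    "speeding",
    "intersection",
    "work_zone",
    "area_type",
    "functional_class",
    "n_lanes",
    "light_condition",
    "surface_condition",
    "pre_crash_stability",
    "season",
    "time_of_day",
    "weather",
    "manner_of_collision",
)

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def age_band(age: float) -> str:
    """Map a driver age in years to its Table-style band, or ``Missing``."""
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return MISSING
    if age < 24:
        return AGE_BANDS[0]
    if age <= 40:
        return AGE_BANDS[1]
    if age <= 65:
        return AGE_BANDS[2]
    return AGE_BANDS[3]


@dataclass(frozen=True)
class CrashRecord:
    """Row-level view of one vehicle-in-fatal-crash observation."""

    crash_id: str
    year: int
    latitude: float
    longitude: float
    fcws_code: str
    bsm_code: str
    n_vehicles: int
    driver_age: float
    gender: str
    drink_drive: int
    speeding: int
    intersection: int
    work_zone: int
    area_type: str
    functional_class: str
    n_lanes: str
    light_condition: str
    surface_condition: str
    pre_crash_stability: str
    season: str
    time_of_day: str
    weather: str
    manner_of_collision: str

    @classmethod
    def from_row(cls, row: Mapping[str, Any]) -> "CrashRecord":
        return cls(**{f.name: row[f.name] for f in fields(cls)})


def records_to_frame(records: list[CrashRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(COLUMNS))


def frame_to_records(table: pd.DataFrame) -> list[CrashRecord]:
    return [CrashRecord.from_row(row) for row in table.to_dict("records")]


def coerce_enum(value: Any, allowed: tuple[str, ...]) -> str:
    """Return ``value`` if it is an allowed category, else ``Missing``."""
    if isinstance(value, str):
        v = value.strip()
        if v in allowed:
            return v
    return MISSING


def coerce_flag(value: Any) -> float:
    """Parse a 0/1 flag; unparseable values become NaN (missing)."""
    if isinstance(value, (bool, np.bool_)):
        return float(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        if value in (0, 1):
            return float(value)
        return np.nan
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _TRUE:
            return 1.0
        if v in _FALSE:
            return 0.0
        try:
            num = float(v)
        except ValueError:
            return np.nan
        if num in (0.0, 1.0):
            return num
    return np.nan
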