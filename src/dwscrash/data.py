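"""Reading, filtering and encoding of vehicle-in-fatal-crash tables.

The ordinal outcome counts the driver warning systems (DWS) standard-fitted
on the vehicle: 0 (neither FCWS nor BSM), 1 (either), 2 (both), derived from
VIN availability codes.  Vehicles whose codes are "Optional" or missing are
excluded — optional fitment makes actual presence unknowable from the VIN.
Only multivehicle crashes are analysed, and rows with missing model
covariates are dropped listwise (with a warning when the missing share
exceeds 2%, past which listwise deletion risks bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .schema import MISSING

__all__ = [
    "SchemaError",
    "EmptyInputError",
    "EmptySampleError",
    "MissingDataWarning",
    "FilterReport",
    "DesignMatrix",
    "read_crash_table",
    "derive_dws_count",
    "add_dws_outcome",
    "apply_filters",
    "code_temporal",
    "encode_design",
    "descriptive_table",
    "percentages_from_counts",
    "DEFAULT_RANDOM_COLUMNS",
    "REFERENCE_LEVELS",
]


class SchemaError(ValueError):
    """Input table does not match the declared column schema."""


class EmptyInputError(ValueError):
    """Input file or table contains no data rows."""


class EmptySampleError(ValueError):
    """All rows were removed by the filtering rules."""


class MissingDataWarning(UserWarning):
    """More than 2% of rows carry missing model covariates."""


#: model covariates that must be non-missing after filtering
MODEL_FIELDS = (
    "year",
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

#: reference (omitted) level per categorical variable
REFERENCE_LEVELS: dict[str, str] = {
    "season": "Summer",
    "time_of_day": "6 a.m.–9 a.m.",
    "manner_of_collision": "Angle",
    "n_lanes": "Two lanes",
    "surface_condition": "Dry",
    "pre_crash_stability": "Tracking",
    "functional_class": "Principal arterial",
    "light_condition": "Daylight",
    "weather": "Clear",
    "gender": "Male",
    "age_band": "≥24, ≤ 40 years",
    "area_type": "Rural",
}

#: design column -> (source column, category) for categorical dummies
_DUMMY_MAP: dict[str, tuple[str, str]] = {
    "urban": ("area_type", "Urban"),
    "season_winter": ("season", "Winter"),
    "season_spring": ("season", "Spring"),
    "season_fall": ("season", "Fall"),
    "tod_12am_3am": ("time_of_day", "12 a.m.–3 a.m."),
    "tod_3am_6am": ("time_of_day", "3 a.m.–6 a.m."),
    "tod_9am_12pm": ("time_of_day", "9 a.m. to 12 p.m."),
    "tod_12pm_3pm": ("time_of_day", "12 p.m.–3 p.m."),
    "tod_3pm_6pm": ("time_of_day", "3 p.m.–6 p.m."),
    "tod_6pm_9pm": ("time_of_day", "6 p.m.–9 p.m."),
    "tod_9pm_12am": ("time_of_day", "9 p.m. to 12 a.m."),
    "col_head_on": ("manner_of_collision", "Head-on"),
    "col_rear_end": ("manner_of_collision", "Rear-end"),
    "col_sideswipe_opposite": ("manner_of_collision", "Sideswipe - opposite direction"),
    "col_sideswipe_same": ("manner_of_collision", "Sideswipe - same direction"),
    "lanes_no_access": ("n_lanes", "No traffic way access"),
    "lanes_one": ("n_lanes", "One lane"),
    "lanes_three": ("n_lanes", "Three lanes"),
    "lanes_four": ("n_lanes", "Four lanes"),
    "lanes_five": ("n_lanes", "Five lanes"),
    "lanes_six": ("n_lanes", "Six lanes"),
    "lanes_seven_plus": ("n_lanes", "Seven or more lanes"),
    "surf_wet": ("surface_condition", "Wet"),
    "surf_ice_snow": ("surface_condition", "Ice, snow, mud, dirt, oil, or water"),
    "stab_skid_lateral": ("pre_crash_stability", "Skidding laterally"),
    "stab_skid_longitudinal": ("pre_crash_stability", "Skidding longitudinally"),
    "stab_not_specific": ("pre_crash_stability", "Not specific"),
    "fc_interstate": ("functional_class", "Interstate"),
    "fc_freeway": ("functional_class", "Freeway or expressway"),
    "fc_minor_arterial": ("functional_class", "Minor arterial"),
    "fc_major_collector": ("functional_class", "Major collector"),
    "fc_minor_collector": ("functional_class", "Minor collector"),
    "fc_local": ("functional_class", "Local"),
    "light_dark": ("light_condition", "Dark"),
    "light_dawn": ("light_condition", "Dawn"),
    "light_dusk": ("light_condition", "Dusk"),
    "weather_cloudy": ("weather", "Cloudy"),
    "weather_rain": ("weather", "Rain"),
    "weather_snow_fog": ("weather", "Snow, fog/smoke/smog, or other adverse condition"),
    "female": ("gender", "Female"),
    "age_lt24": ("age_band", "Less than 24 years"),
    "age_40_65": ("age_band", ">40, ≤ 65 years"),
    "age_gt65": ("age_band", "Greater than 65 years"),
}

#: fixed-role design columns, in reporting order
FIXED_DESIGN_COLUMNS = (
    "const",
    "year_index",
    "urban",
    "season_winter",
    "season_spring",
    "season_fall",
    "tod_12am_3am",
    "tod_3am_6am",
    "tod_9am_12pm",
    "tod_12pm_3pm",
    "tod_3pm_6pm",
    "tod_6pm_9pm",
    "tod_9pm_12am",
    "col_head_on",
    "col_rear_end",
    "col_sideswipe_opposite",
    "col_sideswipe_same",
    "speeding",
    "lanes_no_access",
    "lanes_one",
    "lanes_three",
    "lanes_four",
    "lanes_five",
    "lanes_six",
    "lanes_seven_plus",
    "surf_wet",
    "surf_ice_snow",
    "stab_skid_lateral",
    "stab_skid_longitudinal",
    "stab_not_specific",
    "fc_interstate",
    "fc_freeway",
    "fc_minor_arterial",
    "fc_major_collector",
    "fc_minor_collector",
    "fc_local",
    "intersection",
    "work_zone",
    "light_dark",
    "light_dawn",
    "light_dusk",
    "weather_cloudy",
    "weather_rain",
    "weather_snow_fog",
)

#: driver-behaviour columns given random coefficients, in Cholesky order
DEFAULT_RANDOM_COLUMNS = ("drink_drive", "female", "age_lt24", "age_40_65", "age_gt65")


# ---------------------------------------------------------------------------
# reading

def read_crash_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a flat crash-level CSV into the canonical schema.

    Parameters
    ----------
    path : str or file-like
        CSV with one row per vehicle-in-fatal-crash.  Lines starting with
        ``#`` are treated as comments.
    column_map : dict, optional
        Maps canonical column names to the file's header names.  Unmapped
        columns are looked up under their canonical name.

    Unparseable or out-of-range cells become ``Missing`` (categoricals) or
    NaN (numerics); the row count is preserved.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data rows in {path!r}") from None
    if raw.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path!r}")

    column_map = column_map or {}
    mandatory = [c for c in schema.COLUMNS if c != "crash_id"]
    for canon in mandatory:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(f"input is missing mandatory column {src!r} (for {canon!r})")

    out = pd.DataFrame(index=raw.index)
    id_src = column_map.get("crash_id", "crash_id")
    if id_src in raw.columns:
        out["crash_id"] = raw[id_src].astype(str)
    else:
        out["crash_id"] = [f"r{i:06d}" for i in raw.index]

    def col(canon):
        return raw[column_map.get(canon, canon)]

    for name in schema.NUMERIC_COLUMNS:
        out[name] = pd.to_numeric(col(name).replace("", np.nan), errors="coerce")
    out.loc[~out["latitude"].between(-90, 90), "latitude"] = np.nan
    out.loc[~out["longitude"].between(-180, 180), "longitude"] = np.nan

    for name, allowed in schema.ENUM_COLUMNS.items():
        out[name] = col(name).map(lambda v: schema.coerce_enum(v, allowed))
    for name in schema.FLAG_COLUMNS:
        out[name] = col(name).map(schema.coerce_flag)

    return out[list(schema.COLUMNS)]


# ---------------------------------------------------------------------------
# outcome derivation and filtering

#: sentinel for vehicles excluded by ambiguous availability codes
EXCLUDED = "Excluded"


def derive_dws_count(fcws_code: str, bsm_code: str):
    """Ordinal warning-system count for one vehicle, or ``"Excluded"``.

    2 if both codes are Standard, 1 if exactly one is Standard and the other
    Not Available, 0 if both Not Available.  Any Optional or missing code
    makes actual fitment unknowable, so the vehicle is excluded.
    """
    codes = (fcws_code, bsm_code)
    if any(c not in ("Standard", "Not Available") for c in codes):
        return EXCLUDED
    return sum(c == "Standard" for c in codes)


def add_dws_outcome(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the ordinal ``dws_count`` column (NaN where excluded)."""
    std = {"Standard": 1.0, "Not Available": 0.0}
    f = table["fcws_code"].map(std)
    b = table["bsm_code"].map(std)
    out = table.copy()
    out["dws_count"] = f + b  # NaN propagates for Optional/Missing codes
    return out


@dataclass
class FilterReport:
    """Per-rule tally of rows removed by :func:`apply_filters`."""

    n_input: int
    removed_single_vehicle: int = 0
    removed_optional_dws: int = 0
    removed_unknown: int = 0
    removed_missing: int = 0
    missing_fraction: float = 0.0

    @property
    def n_removed(self) -> int:
        return (
            self.removed_single_vehicle
            + self.removed_optional_dws
            + self.removed_unknown
            + self.removed_missing
        )

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("removed_single_vehicle", self.removed_single_vehicle),
            ("removed_optional_dws", self.removed_optional_dws),
            ("removed_unknown", self.removed_unknown),
            ("removed_missing", self.removed_missing),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def apply_filters(
    table: pd.DataFrame, required: tuple[str, ...] = MODEL_FIELDS
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the sample-definition rules and tally removals per rule.

    Retains rows from multivehicle crashes (``n_vehicles >= 2``) whose DWS
    codes are unambiguous (both Standard or Not Available) and whose model
    covariates in ``required`` are all present.  Each removed row is charged
    to the first rule it violates, in that order.  Warns when the share of
    rows with missing covariates exceeds 2%.
    """
    if table.shape[0] == 0:
        raise EmptyInputError("cannot filter an empty table")
    t = add_dws_outcome(table) if "dws_count" not in table.columns else table

    single = t["n_vehicles"].notna() & (t["n_vehicles"] < 2)
    optional = (t["fcws_code"] == "Optional") | (t["bsm_code"] == "Optional")
    unknown = (t["fcws_code"] == MISSING) | (t["bsm_code"] == MISSING)

    miss = pd.Series(False, index=t.index)
    for name in required:
        if name in ("fcws_code", "bsm_code"):
            continue
        colv = t[name]
        miss |= colv.isna() if colv.dtype.kind == "f" else (colv == MISSING)

    r_single = single
    r_optional = optional & ~r_single
    r_unknown = unknown & ~r_single & ~optional
    r_missing = miss & ~r_single & ~optional & ~unknown

    report = FilterReport(
        n_input=int(t.shape[0]),
        removed_single_vehicle=int(r_single.sum()),
        removed_optional_dws=int(r_optional.sum()),
        removed_unknown=int(r_unknown.sum()),
        removed_missing=int(r_missing.sum()),
        missing_fraction=float(miss.mean()),
    )
    if report.missing_fraction > 0.02:
        warnings.warn(
            f"{100 * report.missing_fraction:.1f}% of rows have missing model "
            "covariates (listwise deletion above 2% may bias the sample)",
            MissingDataWarning,
            stacklevel=2,
        )

    kept = t.loc[~(r_single | r_optional | r_unknown | r_missing)].copy()
    if kept.shape[0] == 0:
        raise EmptySampleError("all rows removed by the filtering rules")
    kept["dws_count"] = kept["dws_count"].astype(int)
    return kept, report


def code_temporal(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the linear year index: 2016 -> 1, ..., 2020 -> 5."""
    years = table["year"]
    bad = years.isna() | (years < schema.YEAR_MIN) | (years > schema.YEAR_MAX)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows have year outside "
            f"[{schema.YEAR_MIN}, {schema.YEAR_MAX}]"
        )
    out = table.copy()
    out["year_index"] = years.astype(int) - (schema.YEAR_MIN - 1)
    return out


# ---------------------------------------------------------------------------
# design encoding

@dataclass
class DesignMatrix:
    """Encoded covariates and ordinal outcome for model estimation.

    ``X`` holds the intercept, the numeric year index and dummy-coded
    covariates; ``roles`` marks each column fixed or random (random columns
    receive normally distributed, mutually correlated coefficients).
    """

    outcome: np.ndarray
    X: pd.DataFrame
    roles: dict[str, str]
    reference_levels: dict[str, str] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=int)
        if not set(np.unique(self.outcome)) <= {0, 1, 2}:
            raise ValueError("outcome values must lie in {0, 1, 2}")
        if self.outcome.shape[0] != self.X.shape[0]:
            raise ValueError("outcome and X row counts differ")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def fixed_columns(self) -> list[str]:
        return [c for c in self.X.columns if self.roles[c] == "fixed"]

    @property
    def random_columns(self) -> list[str]:
        return [c for c in self.X.columns if self.roles[c] == "random"]

    @property
    def X_fixed(self) -> np.ndarray:
        return self.X[self.fixed_columns].to_numpy(float)

    @property
    def X_random(self) -> np.ndarray:
        return self.X[self.random_columns].to_numpy(float)


def encode_design(
    table: pd.DataFrame,
    random_columns: tuple[str, ...] = DEFAULT_RANDOM_COLUMNS,
    drop_constant: bool = True,
) -> DesignMatrix:
    """Dummy-code a filtered crash table into a :class:`DesignMatrix`.

    Reference levels follow :data:`REFERENCE_LEVELS` (Summer, 6–9 a.m.,
    Angle collisions, two lanes, dry surface, tracking, principal arterial,
    daylight, clear weather, male, age 24–40, rural).  The year enters as
    the numeric index 1–5; all-zero dummies (categories absent from the
    sample) are dropped unless they have a random role, which is an error.
    """
    if "dws_count" not in table.columns or "year_index" not in table.columns:
        raise ValueError("table must be filtered (dws_count) and year-coded (year_index)")
    t = table.reset_index(drop=True)
    t = t.assign(age_band=t["driver_age"].map(schema.age_band))

    cols: dict[str, np.ndarray] = {"const": np.ones(len(t))}
    cols["year_index"] = t["year_index"].to_numpy(float)
    for name, (src, category) in _DUMMY_MAP.items():
        cols[name] = (t[src] == category).to_numpy(float)
    for name in ("speeding", "intersection", "work_zone", "drink_drive"):
        cols[name] = t[name].to_numpy(float)

    missing_random = [c for c in random_columns if c not in cols]
    if missing_random:
        raise SchemaError(f"random-role columns not in design: {missing_random}")

    order = [c for c in FIXED_DESIGN_COLUMNS if c not in random_columns]
    order += list(random_columns)
    X = pd.DataFrame({c: cols[c] for c in order})

    dropped: list[str] = []
    if drop_constant:
        for c in list(X.columns):
            if c != "const" and X[c].nunique() <= 1:
                if c in random_columns:
                    raise ValueError(f"random-role column {c!r} is constant in the sample")
                dropped.append(c)
        X = X.drop(columns=dropped)

    roles = {c: ("random" if c in random_columns else "fixed") for c in X.columns}
    return DesignMatrix(
        outcome=t["dws_count"].to_numpy(int),
        X=X,
        roles=roles,
        reference_levels=dict(REFERENCE_LEVELS),
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# descriptive statistics

def percentages_from_counts(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Frequency table with percentages per variable, three-decimal rounding.

    ``counts`` maps variable -> ordered {category: count}; the percentage of
    each category is ``100 * count / N`` for that variable's total, rounded
    to three decimals (so per-variable percentages sum to 100 within 0.01).
    """
    rows = []
    for variable, catcounts in counts.items():
        total = sum(catcounts.values())
        if total == 0:
            raise EmptyInputError(f"variable {variable!r} has zero total count")
        for category, count in catcounts.items():
            rows.append(
                (variable, category, int(count), round(100.0 * count / total, 3))
            )
    return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])


def _descriptive_series(t: pd.DataFrame) -> dict[str, pd.Series]:
    flag = lambda col, yes, no: t[col].map({1.0: yes, 0.0: no, 1: yes, 0: no})
    dws_labels = {0: "No FCWS or BSM", 1: "Either FCWS or BSM", 2: "Both FCWS and BSM"}
    return {
        "DWSs": t["dws_count"].map(dws_labels),
        "Age": t["driver_age"].map(schema.age_band),
        "Drink and drive": flag(
            "drink_drive", "Drink and drive related", "Not related to drink and drive"
        ),
        "Gender": t["gender"],
        "Area type": t["area_type"],
        "Functional class": t["functional_class"],
        "Intersection": flag("intersection", "Intersection", "Non-intersection"),
        "Number of lanes": t["n_lanes"],
        "Work zone": flag("work_zone", "Work zone", "No work zone"),
        "Light condition": t["light_condition"],
        "Pre-crash stability": t["pre_crash_stability"],
        "Surface condition": t["surface_condition"],
        "Season": t["season"],
        "Speeding": flag("speeding", "Speeding", "Not speeding"),
        "Time of the day": t["time_of_day"],
        "Weather condition": t["weather"],
        "Manner of collision": t["manner_of_collision"],
    }


#: declared category order per descriptive variable
_DESCRIPTIVE_ORDER: dict[str, tuple[str, ...]] = {
    "DWSs": ("No FCWS or BSM", "Either FCWS or BSM", "Both FCWS and BSM"),
    "Age": schema.AGE_BANDS,
    "Drink and drive": ("Drink and drive related", "Not related to drink and drive"),
    "Gender": schema.GENDER,
    "Area type": schema.AREA_TYPE,
    "Functional class": schema.FUNCTIONAL_CLASS,
    "Intersection": ("Intersection", "Non-intersection"),
    "Number of lanes": schema.N_LANES,
    "Work zone": ("Work zone", "No work zone"),
    "Light condition": schema.LIGHT_CONDITION,
    "Pre-crash stability": schema.PRE_CRASH_STABILITY,
    "Surface condition": schema.SURFACE_CONDITION,
    "Season": schema.SEASON,
    "Speeding": ("Speeding", "Not speeding"),
    "Time of the day": schema.TIME_OF_DAY,
    "Weather condition": schema.WEATHER,
    "Manner of collision": schema.MANNER_OF_COLLISION,
}


def descriptive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Frequency/percentage table of a filtered sample, one row per category.

    Mirrors the published descriptive layout: every declared category is
    listed (zero counts included) in its declared order, with percentages
    rounded to three decimals.
    """
    if table.shape[0] == 0:
        raise EmptyInputError("cannot describe an empty table")
    if "dws_count" not in table.columns:
        raise ValueError("table must carry dws_count (run apply_filters first)")
    series = _descriptive_series(table)
    counts = {
        variable: {
            cat: int((series[variable] == cat).sum())
            for cat in _DESCRIPTIVE_ORDER[variable]
        }
        for variable in _DESCRIPTIVE_ORDER
    }
    return percentages_from_counts(counts)
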