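"""Published summary statistics of the 2016–2020 FARS multivehicle DWS sample.

The analysis sample behind the default synthetic scenario — FARS fatal-crash
vehicles 2016–2020 with VIN-decoded FCWS/BSM availability, multivehicle
crashes only, spatially matched controls included — is not redistributable,
but its marginal category counts (N = 8757) and the fitted correlated
random-parameters ordered-logit estimates are public.  They parameterize the
default synthetic scenario and serve as reference inputs for the
descriptive-statistics machinery.
"""

from __future__ import annotations

import numpy as np

#: Total observations in the published analysis sample.
PUBLISHED_N = 8757

#: variable -> ordered {category: frequency}.  Counts per variable sum to N.
PUBLISHED_COUNTS: dict[str, dict[str, int]] = {
    "DWSs": {
        "No FCWS or BSM": 6366,
        "Either FCWS or BSM": 1628,
        "Both FCWS and BSM": 763,
    },
    "Age": {
        "Less than 24 years": 1392,
        "≥24, ≤ 40 years": 2765,
        ">40, ≤ 65 years": 3112,
        "Greater than 65 years": 1488,
    },
    "Drink and drive": {
        "Drink and drive related": 923,
        "Not related to drink and drive": 7834,
    },
    "Gender": {"Female": 2781, "Male": 5976},
    "Area type": {"Urban": 5248, "Rural": 3509},
    "Functional class": {
        "Interstate": 1149,
        "Freeway or expressway": 408,
        "Principal arterial": 3394,
        "Minor arterial": 2062,
        "Major collector": 1029,
        "Minor collector": 196,
        "Local": 519,
    },
    "Intersection": {"Intersection": 5231, "Non-intersection": 3526},
    "Number of lanes": {
        "No traffic way access": 84,
        "One lane": 85,
        "Two lanes": 5001,
        "Three lanes": 1281,
        "Four lanes": 1112,
        "Five lanes": 842,
        "Six lanes": 209,
        "Seven or more lanes": 143,
    },
    "Work zone": {"Work zone": 254, "No work zone": 8503},
    "Light condition": {
        "Daylight": 5387,
        "Dark": 3008,
        "Dawn": 173,
        "Dusk": 189,
    },
    "Pre-crash stability": {
        "Tracking": 6682,
        "Skidding laterally": 148,
        "Skidding longitudinally": 103,
        "Not specific": 1824,
    },
    "Surface condition": {
        "Dry": 7483,
        "Wet": 1036,
        "Ice, snow, mud, dirt, oil, or water": 238,
    },
    "Season": {
        "Winter": 1863,
        "Spring": 1939,
        "Summer": 2511,
        "Fall": 2444,
    },
    "Speeding": {"Speeding": 978, "Not speeding": 7779},
    "Time of the day": {
        "12 a.m.–3 a.m.": 597,
        "3 a.m.–6 a.m.": 524,
        "6 a.m.–9 a.m.": 947,
        "9 a.m. to 12 p.m.": 1106,
        "12 p.m.–3 p.m.": 1500,
        "3 p.m.–6 p.m.": 1815,
        "6 p.m.–9 p.m.": 1297,
        "9 p.m. to 12 a.m.": 971,
    },
    "Weather condition": {
        "Clear": 6576,
        "Cloudy": 1281,
        "Rain": 668,
        "Snow, fog/smoke/smog, or other adverse condition": 232,
    },
    "Manner of collision": {
        "Head-on": 2439,
        "Rear-end": 1799,
        "Angle": 3825,
        "Sideswipe - opposite direction": 389,
        "Sideswipe - same direction": 305,
    },
}

#: Fixed-role design columns -> published coefficient (latent-propensity scale).
PUBLISHED_FIXED_BETA: dict[str, float] = {
    "const": -3.898,
    "year_index": 0.584,
    "urban": 0.240,
    "season_winter": -0.086,
    "season_spring": -0.050,
    "season_fall": 0.171,
    "tod_12am_3am": -0.140,
    "tod_3am_6am": -0.204,
    "tod_9am_12pm": 0.306,
    "tod_12pm_3pm": 0.227,
    "tod_3pm_6pm": 0.175,
    "tod_6pm_9pm": 0.106,
    "tod_9pm_12am": -0.047,
    "col_head_on": 0.215,
    "col_rear_end": 0.029,
    "col_sideswipe_opposite": 0.114,
    "col_sideswipe_same": 0.247,
    "speeding": -0.139,
    "lanes_no_access": 0.318,
    "lanes_one": 0.304,
    "lanes_three": 0.025,
    "lanes_four": 0.242,
    "lanes_five": 0.211,
    "lanes_six": 0.165,
    "lanes_seven_plus": 0.268,
    "surf_wet": -0.048,
    "surf_ice_snow": -0.652,
    "stab_skid_lateral": -0.157,
    "stab_skid_longitudinal": -0.483,
    "stab_not_specific": -0.263,
    "fc_interstate": 0.284,
    "fc_freeway": 0.376,
    "fc_minor_arterial": -0.096,
    "fc_major_collector": -0.123,
    "fc_minor_collector": 0.173,
    "fc_local": 0.058,
    "intersection": -0.138,
    "work_zone": 0.160,
    "light_dark": 0.248,
    "light_dawn": -0.175,
    "light_dusk": 0.182,
    "weather_cloudy": -0.041,
    "weather_rain": 0.011,
    "weather_snow_fog": 0.494,
}

#: Random-role columns in Cholesky order, with published coefficient means.
PUBLISHED_RANDOM_MEANS: dict[str, float] = {
    "drink_drive": -0.429,
    "female": 0.684,
    "age_lt24": -0.296,
    "age_40_65": -0.347,
    "age_gt65": 0.196,
}

#: Published lower-triangular Cholesky factor of the random-coefficient
#: covariance, rows/columns ordered as PUBLISHED_RANDOM_MEANS.
PUBLISHED_CHOLESKY = np.array(
    [
        [0.453, 0.000, 0.000, 0.000, 0.000],
        [0.242, 0.779, 0.000, 0.000, 0.000],
        [-0.619, -0.484, 0.387, 0.000, 0.000],
        [-0.890, 0.194, -0.385, 0.383, 0.000],
        [-0.209, -0.912, 0.030, -0.253, 0.197],
    ]
)

#: Upper threshold separating one from two warning systems (lower fixed at 0).
PUBLISHED_PSI1 = 1.644

#: Published fit statistics (reference points, not test targets).
PUBLISHED_LOGLIK_CRP = -6124.668
PUBLISHED_LOGLIK_FIXED = -6138.570
PUBLISHED_PSEUDO_R2_CRP = 0.076
PUBLISHED_PSEUDO_R2_FIXED = 0.074
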