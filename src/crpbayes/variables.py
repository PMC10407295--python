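"""Variable metadata and default calibration targets for the synthetic survey.

The synthetic generator emulates a UK adult household health-assessment
survey in which C-reactive protein (CRP, mg/L) was assayed alongside
socioeconomic and behavioural covariates.  The constants below are the
calibration targets used as generator defaults: per-variable means/SDs and
category proportions, and the latent correlation structure linking the
covariates.
"""

from __future__ import annotations

import numpy as np

# Categorical level orderings. Order matters: cumulative proportions define
# the latent-normal thresholds, and the first level is the modelling
# reference category for the dummy-coded factors.
OCCUPATION_LEVELS = [
    "large_employers_higher_management",
    "higher_professional",
    "lower_management_professional",
    "intermediate",
    "small_employers_own_account",
    "lower_supervisory_technical",
    "semi_routine",
    "routine",
    "not_in_lm",
]

EDUCATION_LEVELS = [
    "degree",
    "other_higher_degree",
    "a_level",
    "gcse",
    "other_qualification",
    "no_qualification",
]

GENDER_LEVELS = ["male", "female"]

HOUSE_LEVELS = ["owned", "rent", "other"]

SRH_LEVELS = ["excellent", "very_good", "good", "fair", "poor"]

SMOKING_LEVELS = ["smoker", "ex_smoker", "non_smoker"]

CATEGORY_LEVELS: dict[str, list[str]] = {
    "occupation": OCCUPATION_LEVELS,
    "education": EDUCATION_LEVELS,
    "gender": GENDER_LEVELS,
    "house_ownership": HOUSE_LEVELS,
    "self_rated_health": SRH_LEVELS,
    "smoking": SMOKING_LEVELS,
}

# Default marginal targets: continuous variables as (mean, sd), categoricals
# as per-level proportions in the level order above.  Proportions are
# renormalised to sum to one at config construction (printed survey tables
# round to three decimals).
DEFAULT_CONTINUOUS_MARGINS: dict[str, tuple[float, float]] = {
    "sport_activity": (3.398, 2.896),
    "age": (52.069, 16.713),
    "gross_income": (1978.723, 1534.189),
    "bmi": (27.960, 5.096),
}

DEFAULT_CATEGORY_PROPORTIONS: dict[str, list[float]] = {
    "occupation": [0.032, 0.044, 0.162, 0.079, 0.055, 0.044, 0.095, 0.055, 0.435],
    "education": [0.221, 0.137, 0.182, 0.197, 0.117, 0.145],
    "gender": [0.441, 0.559],
    "house_ownership": [0.762, 0.225, 0.013],
    "self_rated_health": [0.154, 0.355, 0.287, 0.154, 0.050],
    "smoking": [0.197, 0.403, 0.400],
}

# Hard support bounds for the truncated-normal continuous margins.
CONTINUOUS_BOUNDS: dict[str, tuple[float, float]] = {
    "sport_activity": (-0.5, 10.5),  # rounded to integers 0..10 afterwards
    "age": (16.0, 98.0),
    "bmi": (13.0, 60.0),
}

# Order of the variables in the latent correlation matrix.  CRP appears
# first: its row describes how the response co-varies with the covariates
# but is ignored when drawing covariates (CRP is produced by the response
# model, never by the copula).
CORRELATION_VARIABLES = [
    "crp",
    "occupation",
    "education",
    "gender",
    "house_ownership",
    "self_rated_health",
    "smoking",
    "sport_activity",
    "age",
    "gross_income",
    "bmi",
]

_CORR_LOWER = [
    # crp  occ    edu    gen    house  srh    smoke  sport  age    inc
    [0.15],
    [0.18, 0.44],
    [0.07, 0.05, 0.05],
    [0.09, 0.14, 0.16, 0.04],
    [0.22, 0.27, 0.26, 0.00, 0.15],
    [-0.09, -0.09, -0.15, 0.07, -0.21, -0.17],
    [-0.22, -0.22, -0.25, -0.11, -0.09, -0.37, 0.10],
    [0.16, 0.39, 0.28, -0.04, -0.17, 0.21, 0.04, -0.30],
    [-0.12, -0.41, -0.33, -0.05, -0.18, -0.20, 0.11, 0.17, -0.11],
    [0.37, 0.06, 0.12, 0.00, 0.06, 0.23, 0.02, -0.19, 0.12, -0.08],
]


def default_correlation() -> np.ndarray:
    """Default 11x11 latent correlation matrix over CORRELATION_VARIABLES."""
    k = len(CORRELATION_VARIABLES)
    mat = np.eye(k)
    for i, row in enumerate(_CORR_LOWER, start=1):
        for j, r in enumerate(row):
            mat[i, j] = mat[j, i] = r
    return mat


# Canonical raw-table column order (one row per surveyed person).
RAW_COLUMNS = [
    "crp",
    "height_cm",
    "weight_kg",
    "occupation",
    "education",
    "gender",
    "house_ownership",
    "self_rated_health",
    "smoking",
    "sport_activity",
    "age",
    "gross_income",
    "n_adults",
    "n_children",
]

# Household composition used solely to exercise income equivalization.
ADULT_COUNTS = np.array([1, 2, 3])
ADULT_PROBS = np.array([0.30, 0.60, 0.10])
CHILD_COUNTS = np.array([0, 1, 2])
CHILD_PROBS = np.array([0.60, 0.25, 0.15])
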