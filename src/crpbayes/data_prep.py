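"""Raw survey table -> analysis-ready data.

Implements the sample-construction and measurement pipeline: ordered
exclusions with an audit log, BMI from height/weight, natural-log CRP with
the 3 mg/L low-grade-inflammation flag, OECD household-income
equivalization, z-standardization of the continuous covariates on the
analytic sample, reference-category dummy coding, and descriptive tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import variables as V

#: columns that must be observed for a row to enter the analytic sample
COVARIATE_COLUMNS = [
    "occupation", "education", "gender", "house_ownership",
    "self_rated_health", "smoking", "sport_activity", "age",
    "gross_income", "n_adults", "n_children",
]

#: CRP threshold (mg/L) marking low-grade systemic inflammation
HIGH_RISK_CUTOFF = 3.0

#: OECD equivalence scales: (first adult, additional adult, child) weights
OECD_SCALES = {
    "modified": (1.0, 0.5, 0.3),
    "original": (1.0, 0.7, 0.5),
}

#: continuous design columns, in the order they enter the design matrix
CONTINUOUS_ORDER = ["z_sport", "z_age", "z_income", "z_bmi"]

#: dummy-coded factors with their reference category (first listed level)
DUMMY_FACTORS = ["gender", "house_ownership", "self_rated_health", "smoking"]


class SchemaError(ValueError):
    """Raised when an input table does not match the raw schema."""


@dataclass
class ExclusionLog:
    """Audit log of the ordered exclusion cascade.

    Each dropped row is counted once, under the first reason that applies,
    so ``rows_out + sum(counts) == rows_in`` always holds.
    """

    rows_in: int
    rows_out: int
    counts: dict[str, int] = field(default_factory=dict)

    REASONS = ("crp_missing", "bmi_inapplicable", "crp_nonpositive",
               "covariate_missing")

    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rows_in": self.rows_in, "rows_out": self.rows_out,
                       "counts": self.counts}, fh, indent=2)


@dataclass
class DesignMatrices:
    """Model design: fixed-effect matrix plus group indices.

    Education and occupation enter the models hierarchically (as group
    deviations), so they are carried as integer group indices, not dummies.
    """

    X: np.ndarray                 # n x p fixed-effect matrix
    fixed_names: list[str]
    edu_idx: np.ndarray           # per-row education group index (0..5)
    occ_idx: np.ndarray           # per-row occupation group index (0..8)
    edu_levels: list[str]
    occ_levels: list[str]
    references: dict[str, str]    # factor -> reference category

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_edu(self) -> int:
        return len(self.edu_levels)

    @property
    def n_occ(self) -> int:
        return len(self.occ_levels)


def _check_schema(raw: pd.DataFrame) -> None:
    missing = set(V.RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"raw table lacks columns: {sorted(missing)}")


def apply_exclusions(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop unusable rows in a fixed order, recording one reason per row.

    Order: missing CRP; inapplicable height/weight (BMI undefined);
    non-positive CRP (log undefined); any missing covariate.
    """
    _check_schema(raw)
    n_in = len(raw)
    crp = pd.to_numeric(raw["crp"], errors="coerce")
    height = pd.to_numeric(raw["height_cm"], errors="coerce")
    weight = pd.to_numeric(raw["weight_kg"], errors="coerce")

    crp_missing = crp.isna()
    bmi_bad = (height.isna() | weight.isna() | (height <= 0) | (weight <= 0))
    crp_nonpos = crp <= 0
    cov_missing = raw[COVARIATE_COLUMNS].isna().any(axis=1)

    reason = pd.Series("", index=raw.index)
    for name, mask in [("crp_missing", crp_missing),
                       ("bmi_inapplicable", bmi_bad),
                       ("crp_nonpositive", crp_nonpos.fillna(False)),
                       ("covariate_missing", cov_missing)]:
        reason = reason.mask((reason == "") & mask, name)

    counts = {name: int((reason == name).sum()) for name in ExclusionLog.REASONS}
    counts = {k: v for k, v in counts.items()}
    kept = raw.loc[reason == ""].copy()
    log = ExclusionLog(rows_in=n_in, rows_out=len(kept), counts=counts)
    if len(kept) == 0:
        raise ValueError(f"no rows survive the exclusion cascade: {counts}")
    return kept, log


def compute_bmi(weight_kg, height_cm):
    """Body-mass index, weight / (height/100)^2; NaN where inputs invalid."""
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bmi = np.where((weight > 0) & (height > 0),
                       weight / (height / 100.0) ** 2, np.nan)
    return bmi if bmi.ndim else float(bmi)


def log_crp(crp_mg_per_l):
    """Natural-log CRP and the strict > 3 mg/L high-risk indicator."""
    crp = np.asarray(crp_mg_per_l, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(crp > 0, np.log(crp), np.nan)
    high_risk = crp > HIGH_RISK_CUTOFF
    if y.ndim == 0:
        return float(y), bool(high_risk)
    return y, high_risk


def equivalize_income(gross_income, n_adults, n_children, scale: str = "modified"):
    """Household income divided by the OECD equivalence factor.

    ``modified`` uses weights 1.0 / 0.5 / 0.3 (first adult / additional
    adult / child); ``original`` the older 1.0 / 0.7 / 0.5 scale.
    """
    if scale not in OECD_SCALES:
        raise ValueError(f"unknown OECD scale {scale!r}")
    first, extra, child = OECD_SCALES[scale]
    adults = np.asarray(n_adults, dtype=float)
    children = np.asarray(n_children, dtype=float)
    if np.any(adults < 1):
        raise ValueError("households must contain at least one adult")
    divisor = first + extra * (adults - 1) + child * children
    out = np.asarray(gross_income, dtype=float) / divisor
    return out if out.ndim else float(out)


def zstandardize(column) -> np.ndarray:
    """(x - mean) / SD with the n-1 sample SD, on the supplied values."""
    x = np.asarray(column, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("z-standardization needs at least two distinct values")
    return (x - x.mean()) / x.std(ddof=1)


def build_analytic(filtered: pd.DataFrame, oecd_scale: str = "modified") -> pd.DataFrame:
    """Complete-case raw rows -> analytic table.

    Adds y = ln CRP, the high-risk flag, BMI, equivalized income, and the
    four z-standardized continuous covariates (moments taken on this
    sample).  Equivalization precedes income standardization.
    """
    df = filtered.copy()
    crp = pd.to_numeric(df["crp"]).to_numpy(dtype=float)
    y, high = log_crp(crp)
    if np.any(~np.isfinite(y)):
        raise ValueError("analytic table requires strictly positive CRP")
    df["y"] = y
    df["high_risk"] = high
    bmi = compute_bmi(df["weight_kg"].to_numpy(dtype=float),
                      df["height_cm"].to_numpy(dtype=float))
    eq_income = equivalize_income(df["gross_income"].to_numpy(dtype=float),
                                  df["n_adults"].to_numpy(dtype=float),
                                  df["n_children"].to_numpy(dtype=float),
                                  scale=oecd_scale)
    df["bmi"] = bmi
    df["eq_income"] = eq_income
    df["z_sport"] = zstandardize(df["sport_activity"])
    df["z_age"] = zstandardize(df["age"])
    df["z_income"] = zstandardize(eq_income)
    df["z_bmi"] = zstandardize(bmi)
    for factor, levels in V.CATEGORY_LEVELS.items():
        bad = set(df[factor].unique()) - set(levels)
        if bad:
            raise ValueError(f"unseen {factor} categories: {sorted(bad)}")
    return df


def prepare(raw: pd.DataFrame, oecd_scale: str = "modified"
            ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full pipeline: exclusions then analytic-table construction."""
    kept, log = apply_exclusions(raw)
    return build_analytic(kept, oecd_scale=oecd_scale), log


def encode_design(analytic: pd.DataFrame) -> DesignMatrices:
    """Analytic table -> fixed-effect matrix and hierarchical group indices.

    Dummy factors are coded against their reference category (male, owner,
    excellent health, current smoker); continuous columns follow in the
    order sport, age, income, BMI.
    """
    cols = []
    names = []
    references = {}
    for factor in DUMMY_FACTORS:
        levels = V.CATEGORY_LEVELS[factor]
        references[factor] = levels[0]
        codes = _codes(analytic[factor], levels, factor)
        for k, lvl in enumerate(levels[1:], start=1):
            cols.append((codes == k).astype(float))
            names.append(f"{factor}_{lvl}" if factor != "gender" else f"gender_{lvl}")
    for c in CONTINUOUS_ORDER:
        cols.append(analytic[c].to_numpy(dtype=float))
        names.append(c)
    edu_idx = _codes(analytic["education"], V.EDUCATION_LEVELS, "education")
    occ_idx = _codes(analytic["occupation"], V.OCCUPATION_LEVELS, "occupation")
    references["education"] = V.EDUCATION_LEVELS[0]
    references["occupation"] = V.OCCUPATION_LEVELS[0]
    return DesignMatrices(
        X=np.column_stack(cols), fixed_names=names,
        edu_idx=edu_idx, occ_idx=occ_idx,
        edu_levels=list(V.EDUCATION_LEVELS), occ_levels=list(V.OCCUPATION_LEVELS),
        references=references,
    )


def _codes(series: pd.Series, levels: list[str], factor: str) -> np.ndarray:
    codes = pd.Categorical(series, categories=levels).codes
    if (codes < 0).any():
        bad = sorted(set(series[codes < 0]))
        raise ValueError(f"unseen {factor} categories: {bad}")
    return codes.astype(np.int64)


def descriptives(analytic: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary-statistics and correlation tables for the analytic sample.

    Continuous pairs use product-moment correlation; any pair involving a
    categorical uses Spearman rank correlation on the integer level codes.
    """
    cont = ["y", "sport_activity", "age", "gross_income", "bmi"]
    rows = [{"variable": c, "mean": float(analytic[c].mean()),
             "sd": float(analytic[c].std(ddof=0))} for c in cont]
    for factor, levels in V.CATEGORY_LEVELS.items():
        for lvl in levels:
            p = float((analytic[factor] == lvl).mean())
            rows.append({"variable": f"{factor}:{lvl}", "mean": p,
                         "sd": float(np.sqrt(p * (1 - p)))})
    summary = pd.DataFrame(rows)

    corr_vars = ["y", "occupation", "education", "gender", "house_ownership",
                 "self_rated_health", "smoking", "sport_activity", "age",
                 "gross_income", "bmi"]
    numeric = {}
    categorical = set()
    for v in corr_vars:
        if v in V.CATEGORY_LEVELS:
            numeric[v] = _codes(analytic[v], V.CATEGORY_LEVELS[v], v).astype(float)
            categorical.add(v)
        else:
            numeric[v] = analytic[v].to_numpy(dtype=float)
    k = len(corr_vars)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i):
            a, b = numeric[corr_vars[i]], numeric[corr_vars[j]]
            if np.std(a) == 0 or np.std(b) == 0:
                r = np.nan
            elif corr_vars[i] in categorical or corr_vars[j] in categorical:
                r = spearmanr(a, b).statistic
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            mat[i, j] = mat[j, i] = r
    corr = pd.DataFrame(mat, index=corr_vars, columns=corr_vars)
    return summary, corr
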