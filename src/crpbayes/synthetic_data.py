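"""Synthetic survey generator for the CRP models.

The real analysis sample — a UK household health-assessment panel with a
nurse-collected CRP assay — is access-restricted, so every downstream stage
is exercised on synthetic data instead.  Covariates are drawn from a
Gaussian copula whose latent correlation defaults to the survey's published
covariate correlation structure and whose margins match the published
means/SDs and category proportions.  Responses (log-CRP) are then generated
from Model 1 or Model 2 with configurable "true" parameters, and a raw
fixture reproduces the survey's missingness pattern (9896 records, 521
missing CRP, 283 without usable height/weight, 132 with other missing
covariates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, truncnorm

from . import variables as V
from .data_prep import encode_design, zstandardize, compute_bmi, equivalize_income
from .model_core import Model1Params, Model2Params, linear_predictor

#: height margin (cm) used only to back out weight from generated BMI
_HEIGHT_MEAN, _HEIGHT_SD, _HEIGHT_LO, _HEIGHT_HI = 168.0, 9.5, 140.0, 206.0

#: default raw-fixture composition (rows; see module docstring)
FIXTURE_N = 9896
FIXTURE_CRP_MISSING = 521
FIXTURE_BMI_MISSING = 283
FIXTURE_COV_MISSING = 132


def nearest_positive_definite(mat: np.ndarray, eps: float = 1e-8,
                              tol: float = 0.15) -> np.ndarray:
    """Eigenvalue-clipped repair of a near-correlation matrix.

    Printed 2-d.p. correlation tables are often slightly indefinite; clip
    eigenvalues at ``eps``, rescale to unit diagonal, and refuse matrices
    whose repair moves any entry by more than ``tol``.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= eps:
        return mat
    fixed = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    if np.max(np.abs(fixed - mat)) > tol:
        raise ValueError("correlation matrix is too far from positive definite")
    return fixed


def _default_marginals() -> dict:
    spec: dict = {}
    spec.update({k: tuple(v) for k, v in V.DEFAULT_CONTINUOUS_MARGINS.items()})
    spec.update({k: list(v) for k, v in V.DEFAULT_CATEGORY_PROPORTIONS.items()})
    return spec


@dataclass
class GeneratorConfig:
    """Configuration of the copula generator.

    ``marginal_spec`` maps variable name to either ``(mean, sd)`` for a
    continuous margin or a list of category proportions (renormalised to
    sum to one).  ``latent_correlation`` is the 11x11 matrix over
    ``variables.CORRELATION_VARIABLES``; the CRP row is carried for
    completeness but ignored when drawing covariates.
    """

    n: int = 10_000
    marginal_spec: dict = field(default_factory=_default_marginals)
    latent_correlation: np.ndarray = field(default_factory=V.default_correlation)
    truth: object | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        known = set(V.DEFAULT_CONTINUOUS_MARGINS) | set(V.CATEGORY_LEVELS)
        unknown = set(self.marginal_spec) - known
        if unknown:
            raise ValueError(f"unknown variables in marginal_spec: {sorted(unknown)}")
        for var, levels in V.CATEGORY_LEVELS.items():
            props = np.asarray(self.marginal_spec[var], dtype=float)
            if props.size != len(levels) or np.any(props < 0) or props.sum() <= 0:
                raise ValueError(f"invalid proportions for {var}")
            self.marginal_spec[var] = list(props / props.sum())
        self.latent_correlation = nearest_positive_definite(
            np.asarray(self.latent_correlation, dtype=float))
        if self.latent_correlation.shape != (len(V.CORRELATION_VARIABLES),) * 2:
            raise ValueError("latent_correlation must cover the 11 survey variables")


@lru_cache(maxsize=64)
def _truncnorm_match(mean: float, sd: float, lo: float, hi: float
                     ) -> tuple[float, float]:
    """Underlying (mu, sigma) of a truncated normal with the target moments."""

    def gap(p):
        mu, log_s = p
        s = np.exp(log_s)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(gap, x0=[mean, np.log(sd)], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment match failed for "
                           f"mean={mean}, sd={sd} on [{lo}, {hi}]")
    mu, log_s = sol.x
    return float(mu), float(np.exp(log_s))


def _continuous_from_uniform(var: str, u: np.ndarray, mean: float, sd: float
                             ) -> np.ndarray:
    if var == "gross_income":
        # lognormal margin: right-skewed and strictly positive
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2.0
        return np.exp(norm.ppf(u) * np.sqrt(s2) + mu)
    bounds = {**V.CONTINUOUS_BOUNDS, "height": (_HEIGHT_LO, _HEIGHT_HI)}
    lo, hi = bounds[var]
    m, s = _truncnorm_match(mean, sd, lo, hi)
    a, b = (lo - m) / s, (hi - m) / s
    x = truncnorm.ppf(u, a, b, loc=m, scale=s)
    if var == "sport_activity":
        x = np.clip(np.rint(x), 0, 10)
    return x


def generate_covariates(config: GeneratorConfig, return_latent: bool = False):
    """Draw a covariate table from the Gaussian copula.

    Latent normals with the configured correlation are mapped through each
    margin's inverse CDF; categoricals are thresholded at the cumulative
    proportions in their listed level order.  Height, weight and household
    composition (adults/children, used only by income equivalization) are
    drawn independently; weight is backed out from the generated BMI so the
    BMI formula reproduces it exactly.  The CRP column is left missing —
    responses come from :func:`generate_response`.
    """
    rng = np.random.default_rng(config.seed)
    corr = config.latent_correlation
    cov_vars = V.CORRELATION_VARIABLES[1:]  # drop the CRP row
    idx = [V.CORRELATION_VARIABLES.index(v) for v in cov_vars]
    sub = nearest_positive_definite(corr[np.ix_(idx, idx)])
    chol = np.linalg.cholesky(sub)
    z = rng.standard_normal((config.n, len(cov_vars))) @ chol.T
    u = norm.cdf(z)

    data = {}
    for j, var in enumerate(cov_vars):
        if var in V.CATEGORY_LEVELS:
            props = np.asarray(config.marginal_spec[var], dtype=float)
            cum = np.cumsum(props)
            cum[-1] = 1.0
            codes = np.searchsorted(cum, u[:, j], side="left")
            codes = np.clip(codes, 0, len(props) - 1)
            levels = np.asarray(V.CATEGORY_LEVELS[var], dtype=object)
            data[var] = levels[codes]
        else:
            mean, sd = config.marginal_spec[var]
            data[var] = _continuous_from_uniform(var, u[:, j], mean, sd)

    height = _continuous_from_uniform(
        "height", norm.cdf(rng.standard_normal(config.n)),
        _HEIGHT_MEAN, _HEIGHT_SD)
    data["height_cm"] = height
    data["weight_kg"] = data["bmi"] * (height / 100.0) ** 2
    data["n_adults"] = rng.choice(V.ADULT_COUNTS, size=config.n, p=V.ADULT_PROBS)
    data["n_children"] = rng.choice(V.CHILD_COUNTS, size=config.n, p=V.CHILD_PROBS)
    data["crp"] = np.full(config.n, np.nan)

    df = pd.DataFrame({c: data[c] for c in V.RAW_COLUMNS})
    if return_latent:
        latent = pd.DataFrame(z, columns=cov_vars)
        return df, latent
    return df


def design_from_covariates(covariates: pd.DataFrame, oecd_scale: str = "modified"):
    """Complete covariate rows -> design matrices (z-scored on these rows)."""
    df = covariates.copy()
    df["bmi"] = compute_bmi(df["weight_kg"].to_numpy(dtype=float),
                            df["height_cm"].to_numpy(dtype=float))
    eq = equivalize_income(df["gross_income"].to_numpy(dtype=float),
                           df["n_adults"].to_numpy(dtype=float),
                           df["n_children"].to_numpy(dtype=float),
                           scale=oecd_scale)
    df["z_sport"] = zstandardize(df["sport_activity"])
    df["z_age"] = zstandardize(df["age"])
    df["z_income"] = zstandardize(eq)
    df["z_bmi"] = zstandardize(df["bmi"])
    return encode_design(df)


def generate_response(covariates: pd.DataFrame, truth, model: int,
                      seed: int = 0) -> np.ndarray:
    """Draw log-CRP from the generative model and fill the CRP column.

    ``truth`` supplies the generating parameter values; the linear
    predictors act on the same design encoding the fitting pipeline uses
    (z-scores computed on the supplied rows).  Mutates ``covariates`` by
    setting ``crp = exp(y)`` and returns y.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    if truth.nu <= 0:
        raise ValueError("nu must be positive")
    design = design_from_covariates(covariates)
    mu = linear_predictor(truth, design, side="mu")
    if model == 1:
        if truth.sigma <= 0:
            raise ValueError("sigma must be positive")
        scale = truth.sigma
    else:
        scale = np.exp(linear_predictor(truth, design, side="sigma"))
    rng = np.random.default_rng(seed)
    y = mu + scale * rng.standard_t(truth.nu, size=design.n)
    covariates["crp"] = np.exp(y)
    return y


def model1_reference_truth() -> Model1Params:
    """Default generating values for Model 1 simulation studies.

    Calibrated to the posterior means reported for the homoscedastic model
    on the real survey, so synthetic data resembles the real outcome
    distribution.
    """
    return Model1Params(
        beta0=0.379,
        beta_fixed=np.array([0.150, 0.062, 0.063,            # female, rent, other
                             0.079, 0.084, 0.198, 0.333,     # SRH vs excellent
                             -0.221, -0.257,                 # ex-/non-smoker
                             -0.075, 0.085, -0.015, 0.386]), # sport, age, income, BMI
        u_edu=np.array([-0.057, -0.038, 0.003, -0.034, 0.038, 0.086]),
        u_occ=np.array([-0.043, 0.006, 0.0001, -0.023, -0.052,
                        0.007, 0.030, 0.026, 0.052]),
        sd_edu=0.087, sd_occ=0.055, sigma=0.876, nu=9.747,
    )


def model2_reference_truth() -> Model2Params:
    """Default generating values for Model 2 (distributional) simulations."""
    return Model2Params(
        beta0=0.370,
        beta_fixed=np.array([0.159, 0.059, 0.058,
                             0.083, 0.090, 0.203, 0.338,
                             -0.220, -0.261,
                             -0.058, 0.080, -0.015, 0.386]),
        u_edu=np.array([-0.052, -0.032, 0.006, -0.029, 0.034, 0.080]),
        u_occ=np.array([-0.043, 0.004, -0.000, -0.024, -0.056,
                        0.007, 0.029, 0.027, 0.058]),
        sd_edu=0.079, sd_occ=0.057,
        gamma0=-0.155,
        gamma_fixed=np.array([0.022, 0.012, 0.008,
                              0.047, 0.056, 0.095, 0.064,
                              -0.058, -0.089,
                              -0.089, -0.027, -0.004, -0.040]),
        v_edu=np.array([-0.006, -0.007, 0.007, -0.015, 0.017, 0.004]),
        v_occ=np.array([-0.020, 0.037, -0.028, -0.007, -0.057,
                        0.011, 0.016, -0.009, 0.057]),
        sd_v_edu=0.024, sd_v_occ=0.052, nu=10.357,
    )


def generate_raw_fixture(seed: int = 0, n: int = FIXTURE_N,
                         n_crp_missing: int = FIXTURE_CRP_MISSING,
                         n_bmi_missing: int = FIXTURE_BMI_MISSING,
                         n_cov_missing: int = FIXTURE_COV_MISSING
                         ) -> pd.DataFrame:
    """Raw pre-exclusion table with the survey's missingness pattern.

    Three pairwise-disjoint row sets are blanked: CRP missing; height and
    weight inapplicable; one further covariate missing.  All remaining rows
    are complete, so the exclusion cascade retains exactly
    ``n - n_crp_missing - n_bmi_missing - n_cov_missing`` rows.
    """
    if n_crp_missing + n_bmi_missing + n_cov_missing > n:
        raise ValueError("missingness counts exceed the table size")
    config = GeneratorConfig(n=n, seed=seed)
    df = generate_covariates(config)
    generate_response(df, model1_reference_truth(), model=1, seed=seed + 1)

    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(n)
    crp_rows = order[:n_crp_missing]
    bmi_rows = order[n_crp_missing:n_crp_missing + n_bmi_missing]
    cov_rows = order[n_crp_missing + n_bmi_missing:
                     n_crp_missing + n_bmi_missing + n_cov_missing]

    df.loc[df.index[crp_rows], "crp"] = np.nan
    df.loc[df.index[bmi_rows], ["height_cm", "weight_kg"]] = np.nan
    blankable = ["occupation", "education", "gender", "house_ownership",
                 "self_rated_health", "smoking", "sport_activity", "age",
                 "gross_income"]
    which = rng.integers(0, len(blankable), size=n_cov_missing)
    for row, col_i in zip(cov_rows, which):
        df.iloc[row, df.columns.get_loc(blankable[col_i])] = np.nan
    return df


def write_raw_csv(df: pd.DataFrame, path, config: GeneratorConfig | None = None
                  ) -> None:
    """Write a raw table as CSV (missing cells empty) plus a sidecar JSON."""
    df.to_csv(path, index=False, na_rep="")
    meta = {"columns": list(df.columns), "n": int(len(df))}
    if config is not None:
        meta["seed"] = int(config.seed)
        meta["marginal_spec"] = {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in config.marginal_spec.items()}
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_raw_csv(path) -> pd.DataFrame:
    """Read a raw table written by :func:`write_raw_csv`."""
    df = pd.read_csv(path)
    missing = set(V.RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"raw CSV lacks columns: {sorted(missing)}")
    return df
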