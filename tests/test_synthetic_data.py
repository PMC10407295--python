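"""Generator: copula calibration, response model, missingness fixture."""

import numpy as np
import pandas as pd
import pytest

import crpbayes as cb
from crpbayes import variables as V
from crpbayes import data_prep as dp
from crpbayes import model_core as mc
from crpbayes.synthetic_data import (
    FIXTURE_BMI_MISSING,
    FIXTURE_COV_MISSING,
    FIXTURE_CRP_MISSING,
    FIXTURE_N,
    design_from_covariates,
    nearest_positive_definite,
)


@pytest.fixture(scope="module")
def big_sample():
    config = cb.GeneratorConfig(n=100_000, seed=5)
    return cb.generate_covariates(config, return_latent=True)


class TestGeneratorConfig:
    def test_proportions_renormalised(self):
        config = cb.GeneratorConfig(n=10)
        for var in V.CATEGORY_LEVELS:
            assert np.isclose(sum(config.marginal_spec[var]), 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cb.GeneratorConfig(n=0)
        with pytest.raises(ValueError):
            cb.GeneratorConfig(n=10, marginal_spec={"not_a_variable": (0, 1)})
        bad = V.default_correlation()
        bad[1, 2] = 0.99  # asymmetric
        with pytest.raises(ValueError):
            cb.GeneratorConfig(n=10, latent_correlation=bad)

    def test_far_from_pd_matrix_rejected(self):
        k = len(V.CORRELATION_VARIABLES)
        mat = np.full((k, k), 0.9)
        mat[0, 1] = mat[1, 0] = -0.9  # wildly inconsistent
        np.fill_diagonal(mat, 1.0)
        with pytest.raises(ValueError, match="positive definite"):
            nearest_positive_definite(mat)

    def test_printed_matrix_repaired_to_pd(self):
        fixed = nearest_positive_definite(V.default_correlation())
        vals = np.linalg.eigvalsh(fixed)
        assert vals.min() > 0
        assert np.allclose(np.diag(fixed), 1.0)


class TestCovariates:
    def test_seed_determinism(self):
        a = cb.generate_covariates(cb.GeneratorConfig(n=500, seed=9))
        b = cb.generate_covariates(cb.GeneratorConfig(n=500, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_female_proportion(self):
        df = cb.generate_covariates(cb.GeneratorConfig(n=10_000, seed=1))
        assert (df["gender"] == "female").mean() == pytest.approx(0.559, abs=0.02)

    def test_latent_education_occupation_correlation(self, big_sample):
        _, latent = big_sample
        r = np.corrcoef(latent["education"], latent["occupation"])[0, 1]
        assert r == pytest.approx(0.44, abs=0.05)

    def test_continuous_margins_calibrated(self, big_sample):
        df, _ = big_sample
        df = df.copy()
        df["bmi"] = dp.compute_bmi(df["weight_kg"], df["height_cm"])
        for var, (mean, sd) in V.DEFAULT_CONTINUOUS_MARGINS.items():
            col = "bmi" if var == "bmi" else var
            x = df[col].to_numpy(dtype=float)
            assert x.mean() == pytest.approx(mean, rel=0.02), var
            assert x.std(ddof=1) == pytest.approx(sd, rel=0.02), var

    def test_category_proportions_calibrated(self, big_sample):
        df, _ = big_sample
        for var, props in V.DEFAULT_CATEGORY_PROPORTIONS.items():
            targets = np.asarray(props) / np.sum(props)
            for lvl, p in zip(V.CATEGORY_LEVELS[var], targets):
                assert (df[var] == lvl).mean() == pytest.approx(p, abs=0.01), (var, lvl)

    def test_sport_is_integer_in_range(self, big_sample):
        df, _ = big_sample
        sport = df["sport_activity"].to_numpy(dtype=float)
        assert np.all(sport == np.rint(sport))
        assert sport.min() >= 0 and sport.max() <= 10

    def test_age_within_truncation_bounds(self, big_sample):
        df, _ = big_sample
        assert df["age"].min() >= 16 and df["age"].max() <= 98


class TestResponse:
    def test_degenerate_scale_concentrates_at_intercept(self, small_raw):
        df = small_raw.copy()
        truth = cb.Model1Params(
            beta0=1.7, beta_fixed=np.zeros(13), u_edu=np.zeros(6),
            u_occ=np.zeros(9), sd_edu=0.1, sd_occ=0.1, sigma=1e-9, nu=10.0)
        y = cb.generate_response(df, truth, model=1, seed=3)
        assert np.allclose(y, 1.7, atol=1e-6)

    def test_residual_sd_matches_student_t_variance(self):
        # SD of a scale-sigma Student-t is sigma * sqrt(nu / (nu - 2))
        df = cb.generate_covariates(cb.GeneratorConfig(n=100_000, seed=6))
        truth = cb.model1_reference_truth()
        y = cb.generate_response(df, truth, model=1, seed=7)
        design = design_from_covariates(df)
        resid = y - mc.linear_predictor(truth, design, side="mu")
        expected = 0.876 * np.sqrt(9.747 / 7.747)
        assert resid.std() == pytest.approx(expected, abs=0.03)

    def test_model2_nests_model1_moments(self):
        # scale-side coefficients at zero reduce Model 2 to Model 1
        n = 100_000
        df1 = cb.generate_covariates(cb.GeneratorConfig(n=n, seed=8))
        df2 = df1.copy()
        t1 = cb.model1_reference_truth()
        t2 = cb.Model2Params(
            beta0=t1.beta0, beta_fixed=t1.beta_fixed, u_edu=t1.u_edu,
            u_occ=t1.u_occ, sd_edu=t1.sd_edu, sd_occ=t1.sd_occ,
            gamma0=np.log(t1.sigma), gamma_fixed=np.zeros(13),
            v_edu=np.zeros(6), v_occ=np.zeros(9),
            sd_v_edu=0.01, sd_v_occ=0.01, nu=t1.nu)
        y1 = cb.generate_response(df1, t1, model=1, seed=9)
        y2 = cb.generate_response(df2, t2, model=2, seed=10)
        assert y1.mean() == pytest.approx(y2.mean(), abs=0.02)
        assert y1.std() == pytest.approx(y2.std(), abs=0.02)

    def test_invalid_truth_rejected(self, small_raw):
        df = small_raw.copy()
        bad = cb.model1_reference_truth()
        bad.nu = -1.0
        with pytest.raises(ValueError):
            cb.generate_response(df, bad, model=1, seed=1)
        bad = cb.model1_reference_truth()
        bad.sigma = 0.0
        with pytest.raises(ValueError):
            cb.generate_response(df, bad, model=1, seed=1)


@pytest.fixture(scope="module")
def fixture():
    return cb.generate_raw_fixture(seed=42)


class TestRawFixture:
    def test_row_and_missingness_counts(self, fixture):
        assert len(fixture) == FIXTURE_N == 9896
        crp_missing = fixture["crp"].isna()
        assert int(crp_missing.sum()) == FIXTURE_CRP_MISSING == 521
        bmi_missing = fixture["height_cm"].isna() & ~crp_missing
        assert int(bmi_missing.sum()) == FIXTURE_BMI_MISSING == 283

    def test_missingness_sets_disjoint(self, fixture):
        crp_m = fixture["crp"].isna()
        bmi_m = fixture["height_cm"].isna() | fixture["weight_kg"].isna()
        cov_m = fixture[dp.COVARIATE_COLUMNS].isna().any(axis=1)
        assert int((crp_m & bmi_m).sum()) == 0
        assert int((crp_m & cov_m).sum()) == 0
        assert int((bmi_m & cov_m).sum()) == 0
        union = int((crp_m | bmi_m | cov_m).sum())
        assert union == FIXTURE_CRP_MISSING + FIXTURE_BMI_MISSING + FIXTURE_COV_MISSING

    def test_covariate_missing_count_and_completeness(self, fixture):
        crp_m = fixture["crp"].isna()
        bmi_m = fixture["height_cm"].isna()
        cov_m = fixture[dp.COVARIATE_COLUMNS].isna().any(axis=1)
        assert int((cov_m & ~crp_m & ~bmi_m).sum()) == FIXTURE_COV_MISSING == 132
        complete = fixture[~(crp_m | bmi_m | cov_m)]
        assert not complete.isna().any().any()
        assert (pd.to_numeric(complete["crp"]) > 0).all()


class TestRoundTrip:
    def test_csv_round_trip(self, small_raw, tmp_path):
        from crpbayes.synthetic_data import read_raw_csv, write_raw_csv
        path = tmp_path / "raw.csv"
        config = cb.GeneratorConfig(n=400, seed=101)
        write_raw_csv(small_raw, path, config)
        back = read_raw_csv(path)
        assert list(back.columns) == list(small_raw.columns)
        assert np.allclose(back["crp"], small_raw["crp"])
        assert (path.parent / "raw.csv.json").exists()


class TestGenerativeConsistency:
    def test_credible_interval_coverage_over_replicates(self):
        """Fitting Model 1 to its own simulations: the 90% central credible
        interval should cover each true fixed coefficient in >= 14 of 20
        seeded replicates (exact 90% coverage gives ~18/20 on average)."""
        from crpbayes.sampler import SamplerConfig, run_chains

        truth = cb.model1_reference_truth()
        true_vals = np.concatenate([[truth.beta0], truth.beta_fixed])
        hits = np.zeros(true_vals.size, dtype=int)
        for rep in range(20):
            seed = 1000 + 10 * rep
            df = cb.generate_covariates(cb.GeneratorConfig(n=2000, seed=seed))
            cb.generate_response(df, truth, model=1, seed=seed + 1)
            analytic, _ = cb.prepare(df)
            design = cb.encode_design(analytic)
            y = analytic["y"].to_numpy(dtype=float)
            target = mc.PosteriorTarget(
                y, design, mc.PriorConfig.from_response(y), 1)
            cs = run_chains(target.logp, target.grad,
                            SamplerConfig(seed=seed + 2, n_chains=2,
                                          n_iterations=1500, n_warmup=750),
                            target.dim, constrain=target.constrain,
                            names=target.constrained_names)
            for j, name in enumerate(["intercept"] + design.fixed_names):
                draws = cs.pooled(name)
                lo, hi = np.quantile(draws, [0.05, 0.95])
                hits[j] += int(lo <= true_vals[j] <= hi)
        assert np.all(hits >= 14), dict(zip(["intercept"] + [f"b{j}" for j in range(13)], hits))
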