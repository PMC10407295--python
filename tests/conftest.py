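"""Shared fixtures: small synthetic datasets and prepared designs.

Session scope keeps the generator and preparation work out of every test's
inner loop; all randomness is seeded.
"""

import numpy as np
import pytest

import crpbayes as cb
from crpbayes import model_core as mc


@pytest.fixture(scope="session")
def small_raw():
    """400 complete synthetic records with Model 1 responses."""
    config = cb.GeneratorConfig(n=400, seed=101)
    df = cb.generate_covariates(config)
    cb.generate_response(df, cb.model1_reference_truth(), model=1, seed=102)
    return df


@pytest.fixture(scope="session")
def prepared(small_raw):
    """(analytic table, design, y) for the 400-record dataset."""
    analytic, _ = cb.prepare(small_raw)
    design = cb.encode_design(analytic)
    return analytic, design, analytic["y"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def prior(prepared):
    _, _, y = prepared
    return mc.PriorConfig.from_response(y)


@pytest.fixture(scope="session")
def target_m1(prepared, prior):
    _, design, y = prepared
    return mc.PosteriorTarget(y, design, prior, model=1)


@pytest.fixture(scope="session")
def target_m2(prepared, prior):
    _, design, y = prepared
    return mc.PosteriorTarget(y, design, prior, model=2)


@pytest.fixture(scope="session")
def iid_chains():
    """4 chains x 1000 iid standard-normal draws."""
    rng = np.random.default_rng(2024)
    return rng.standard_normal((4, 1000))
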