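import numpy as np
import pytest

from ieg import synthetic
from ieg.evaluation import CVData


@pytest.fixture(scope="session")
def small_sites():
    return synthetic.gen_sites(60, 6, 25.0, (600.0, 600.0), seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """60-site dataset with 4 informative of 30 covariates and known truth."""
    sites = synthetic.gen_sites(60, 6, 25.0, (600.0, 600.0), seed=11)
    covs, truth = synthetic.gen_covariates(sites, 30, 4, seed=12)
    conc = synthetic.gen_concentrations(sites, covs, truth, field_seed=13)
    data = CVData(
        site_ids=sites["site_id"].to_numpy(),
        coords=sites[["x", "y"]].to_numpy(float),
        covariates=covs.drop(columns="site_id").to_numpy(float),
        y_sqrt=conc.records["sqrt_value"].to_numpy(),
        y_native=conc.records["value"].to_numpy(),
    )
    return data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
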