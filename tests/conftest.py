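import numpy as np
import pytest

import pbpkgsa as pg


@pytest.fixture(scope="session")
def prior_table():
    return pg.load_prior_table()


@pytest.fixture(scope="session")
def nominal_params(prior_table):
    return pg.build_default_parameters(prior_table)


@pytest.fixture(scope="session")
def small_dataset(nominal_params):
    """Two-study synthetic dataset generated at the nominal parameters."""
    designs = [
        d for d in pg.default_designs() if d.study_id in ("1000mg_a", "20mgkg_a")
    ]
    return pg.generate_dataset(nominal_params, designs, seed=101)


@pytest.fixture(scope="session")
def gsa_times():
    return np.asarray(pg.GSA_TIMES)
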