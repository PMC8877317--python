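import numpy as np
import pytest

from formulab import datasets
from formulab.scheffe import fit_scheffe

#: quadratic coefficient vectors reported for the published 16-run study,
#: used as independent oracles for the refit and pseudo-coding checks
PUBLISHED_SIZE_COEFFS = np.array([49.91, 42.96, 88.44, -30.24, -68.56, -80.96])
PUBLISHED_EE_COEFFS = np.array([105.52, 93.43, -5.04, -74.19, 42.05, 67.93])


@pytest.fixture(scope="session")
def coding():
    return datasets.pseudo_coding()


@pytest.fixture(scope="session")
def constraints():
    return datasets.mixture_constraints()


@pytest.fixture(scope="session")
def size_fit(coding):
    return fit_scheffe(datasets.response_table("size_nm"), coding)


@pytest.fixture(scope="session")
def ee_fit(coding):
    return fit_scheffe(datasets.response_table("ee_pct"), coding)


@pytest.fixture(scope="session")
def optimum_fraction():
    return np.array(datasets.OPTIMUM_PCT) / 100.0
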