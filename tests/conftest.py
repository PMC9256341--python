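import numpy as np
import pytest

import nbu2test as nt


@pytest.fixture(scope="session")
def leukemia():
    return nt.load_dataset("leukemia")


@pytest.fixture(scope="session")
def liver_complete():
    return nt.load_dataset("liver_complete")


@pytest.fixture(scope="session")
def liver_censored():
    return nt.load_dataset("liver_censored")


@pytest.fixture(scope="session")
def lung_cancer():
    return nt.load_dataset("lung_cancer")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
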