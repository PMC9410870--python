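import numpy as np
import pytest

import tihlburr as t

# parameter sets spanning each coordinate over [0.3, 5], used by the
# normalization / consistency grids
PARAM_GRID = [
    (0.3, 0.3, 0.3, 0.3),
    (5.0, 5.0, 5.0, 5.0),
    (1.2, 0.5, 1.5, 1.5),
    (1.2, 2.0, 1.5, 1.5),
    (1.2, 0.5, 3.0, 1.5),
    (1.2, 2.0, 3.0, 1.5),
    (3.0, 0.5, 1.5, 0.5),
    (3.0, 2.0, 3.0, 0.5),
    (0.3, 1.0, 1.0, 2.0),
    (5.0, 0.5, 1.0, 1.0),
    (0.5, 5.0, 1.0, 1.0),
    (1.0, 1.0, 5.0, 0.3),
    (1.0, 1.0, 0.3, 5.0),
    (2.0, 0.3, 2.0, 2.0),
    (0.7, 0.7, 0.7, 0.7),
    (4.0, 1.5, 0.5, 2.5),
    (1.5, 4.0, 2.5, 0.5),
    (2.5, 2.5, 1.0, 3.0),
    (0.4, 1.8, 4.0, 0.8),
    (3.5, 0.9, 0.9, 3.5),
]

# printed parameter rows of the two applications
TABLE3_SAUDI = (48.1999, 2.1852, 1.4615, 67.4952)
TABLE4_ITALY = (1.1716, 0.8199, 0.5148, 1.8929)


@pytest.fixture(scope="session")
def default_params():
    return t.tihlbw_params(1.2, 0.5, 1.5, 1.5)


@pytest.fixture(scope="session")
def italy_params():
    return t.tihlbw_params(*TABLE4_ITALY)


@pytest.fixture(scope="session")
def saudi_params():
    return t.tihlbw_params(*TABLE3_SAUDI)


@pytest.fixture(scope="session")
def italy():
    return t.load_dataset("italy").values


@pytest.fixture(scope="session")
def saudi():
    return t.load_dataset("saudi_arabia").values


@pytest.fixture(scope="session")
def italy_fit(italy):
    """The multi-start constrained MLE on the Italy data (computed once)."""
    return t.fit_mle(italy, "tihlbw", n_starts=20, seed=0)
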