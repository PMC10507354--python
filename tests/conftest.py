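import os

# keep BLAS reductions deterministic and avoid oversubscription
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest

from roqdce.core import TimeGrid
from roqdce.pk import AIFModelParams, population_aif


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def aif_params():
    return AIFModelParams()


@pytest.fixture(scope="session")
def aif(grid, aif_params):
    return population_aif(aif_params, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
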