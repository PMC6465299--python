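import logging

import numpy as np
import pytest

from hergqc.params import NOISELESS, KineticParams, NoiseModel
from hergqc.presets import load_presets

# Noiseless simulated plates legitimately lack isotype wells; keep the suite quiet.
logging.getLogger("hergqc.estimators").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def preset_lib():
    return load_presets()


@pytest.fixture(scope="session")
def wt_params(preset_lib):
    return preset_lib.params("WT")


@pytest.fixture(scope="session")
def t65p_params(preset_lib):
    return preset_lib.params("T65P")


@pytest.fixture
def noiseless():
    return NOISELESS


@pytest.fixture
def default_noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def random_param_sets():
    """100 random but physiological rate-constant sets for oracle comparisons."""
    rng = np.random.default_rng(20240917)
    sets = []
    for i in range(100):
        sets.append(
            KineticParams(
                construct_name=f"rand{i}",
                k_mat=rng.uniform(0.05, 1.5),
                k_erad=rng.uniform(0.0, 1.5),
                k_int=rng.uniform(0.002, 0.3),
                k_rec=rng.uniform(0.0, 0.2),
                k_lys=rng.uniform(0.0005, 0.1),
                k_pm=rng.uniform(0.02, 0.6),
                temp_factor=rng.uniform(1.0, 3.0),
            )
        )
    return sets
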